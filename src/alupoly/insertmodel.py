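"""Insert-size distribution machinery.

The spacing between the two ends of a paired-end fragment (the *outer*
distance, rightmost end minus leftmost start) follows a distribution ``Y``
that is a property of the sequencing library.  All genotyping in this
package is built on likelihoods under ``Y`` and under its shift
``Z = Y + l_Alu``: a read pair spanning a locus where a mobile element of
length ``l_Alu`` is absent from the sample (but present in the reference
the reads were mapped to) shows an insert drawn from ``Z`` rather than
``Y``.

The model carries the ``epsilon`` quantiles ``q_lo = Y_eps`` and
``q_hi = Y_{1-eps}`` (default ``epsilon = 0.005``) which bound what counts
as a *proper* pair and size all scan windows downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

__all__ = [
    "DENSITY_FLOOR",
    "InsertSizeModel",
    "estimate_insert_model",
    "density",
    "shifted_density",
]

#: Lower bound applied to every density evaluation so that products over
#: many read pairs keep finite log-likelihoods.
DENSITY_FLOOR = 1e-300

MIN_PROPER_PAIRS = 100


class DegenerateInsertDistributionError(ValueError):
    """Raised when the observed insert lengths carry no spread."""


class TooFewPairsError(ValueError):
    """Raised when fewer pairs than the required minimum are supplied."""


@dataclass
class InsertSizeModel:
    """Distribution of paired-end outer insert lengths.

    Parameters
    ----------
    mean, sd
        Location/scale in bp.  For the empirical form these are the robust
        estimates used to summarise the histogram.
    epsilon
        Tail mass used for the proper-pair quantiles, in (0, 0.5).
    q_lo, q_hi
        The ``epsilon`` and ``1 - epsilon`` quantiles of Y in bp.
    form
        ``"gaussian"`` (default) or ``"empirical"``.  The empirical form
        keeps a smoothed histogram of the training inserts.
    """

    mean: float
    sd: float
    epsilon: float = 0.005
    q_lo: float = field(default=None)  # type: ignore[assignment]
    q_hi: float = field(default=None)  # type: ignore[assignment]
    form: str = "gaussian"
    _hist_edges: Optional[np.ndarray] = field(default=None, repr=False)
    _hist_density: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError(f"epsilon must lie in (0, 0.5), got {self.epsilon}")
        if self.sd <= 0:
            raise DegenerateInsertDistributionError(
                f"insert-size sd must be positive, got {self.sd}"
            )
        if self.q_lo is None:
            self.q_lo = float(stats.norm.ppf(self.epsilon, self.mean, self.sd))
        if self.q_hi is None:
            self.q_hi = float(stats.norm.ppf(1.0 - self.epsilon, self.mean, self.sd))
        if not (self.q_lo < self.mean < self.q_hi):
            raise ValueError(
                f"quantiles must bracket the mean: {self.q_lo}, {self.mean}, {self.q_hi}"
            )

    # -- densities ----------------------------------------------------

    def density(self, t) -> np.ndarray | float:
        """Density of Y at insert length ``t`` (bp), floored at DENSITY_FLOOR."""
        t = np.asarray(t, dtype=float)
        if self.form == "gaussian":
            d = stats.norm.pdf(t, self.mean, self.sd)
        else:
            d = self._empirical_density(t)
        out = np.maximum(d, DENSITY_FLOOR)
        return float(out) if out.ndim == 0 else out

    def log_density(self, t) -> np.ndarray | float:
        d = np.log(self.density(t))
        return float(d) if np.ndim(d) == 0 else d

    def shifted_density(self, t, l_alu: float) -> np.ndarray | float:
        """Density of ``Z = Y + l_alu`` at ``t``; exactly ``density(t - l_alu)``."""
        if l_alu <= 0:
            raise ValueError(f"l_alu must be positive, got {l_alu}")
        return self.density(np.asarray(t, dtype=float) - l_alu)

    def _empirical_density(self, t: np.ndarray) -> np.ndarray:
        edges, dens = self._hist_edges, self._hist_density
        if edges is None or dens is None:
            raise ValueError("empirical form requested but no histogram stored")
        idx = np.searchsorted(edges, t, side="right") - 1
        inside = (idx >= 0) & (idx < len(dens))
        out = np.zeros_like(t, dtype=float)
        out[inside] = dens[idx[inside]]
        return out

    # -- classification helpers --------------------------------------

    def is_proper_length(self, t) -> np.ndarray | bool:
        t = np.asarray(t, dtype=float)
        ok = (t >= self.q_lo) & (t <= self.q_hi)
        return bool(ok) if ok.ndim == 0 else ok

    # -- (de)serialization -------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "form": self.form,
            "mean": self.mean,
            "sd": self.sd,
            "epsilon": self.epsilon,
            "q_lo": self.q_lo,
            "q_hi": self.q_hi,
        }
        if self.form == "empirical":
            d["hist_edges"] = list(map(float, self._hist_edges))
            d["hist_density"] = list(map(float, self._hist_density))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InsertSizeModel":
        kwargs = dict(
            mean=d["mean"], sd=d["sd"], epsilon=d["epsilon"],
            q_lo=d["q_lo"], q_hi=d["q_hi"], form=d["form"],
        )
        if d.get("hist_edges") is not None:
            kwargs["_hist_edges"] = np.asarray(d["hist_edges"], dtype=float)
            kwargs["_hist_density"] = np.asarray(d["hist_density"], dtype=float)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InsertSizeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _insert_lengths(proper_pairs) -> np.ndarray:
    """Accept an array of insert lengths or an iterable of ReadPairRecord."""
    if isinstance(proper_pairs, np.ndarray):
        return proper_pairs.astype(float)
    vals = []
    for p in proper_pairs:
        if hasattr(p, "insert_length"):
            vals.append(p.insert_length)
        else:
            vals.append(float(p))
    return np.asarray(vals, dtype=float)


def estimate_insert_model(
    proper_pairs,
    epsilon: float = 0.005,
    form: str = "gaussian",
) -> InsertSizeModel:
    """Estimate the insert-size model from proper pairs.

    Robust procedure: ``mean`` = median of the insert lengths, ``sd`` =
    1.4826 x MAD, and ``q_lo``/``q_hi`` the empirical ``epsilon`` and
    ``1 - epsilon`` quantiles.  Both Gaussian and empirical density forms
    are available; the result is invariant to the order of the input.

    Parameters
    ----------
    proper_pairs
        Insert lengths (array-like) or an iterable of records exposing
        ``insert_length``.  Only pairs with both ends uniquely mapped on
        one chromosome should be supplied.
    """
    t = _insert_lengths(proper_pairs)
    if len(t) < MIN_PROPER_PAIRS:
        raise TooFewPairsError(
            f"need at least {MIN_PROPER_PAIRS} proper pairs to estimate the "
            f"insert-size model, got {len(t)}"
        )
    med = float(np.median(t))
    mad = float(np.median(np.abs(t - med)))
    sd = 1.4826 * mad
    if sd <= 0:
        raise DegenerateInsertDistributionError(
            "insert lengths are (near-)constant; cannot estimate a spread"
        )
    q_lo = float(np.quantile(t, epsilon))
    q_hi = float(np.quantile(t, 1.0 - epsilon))
    model = InsertSizeModel(
        mean=med, sd=sd, epsilon=epsilon, q_lo=q_lo, q_hi=q_hi, form=form
    )
    if form == "empirical":
        lo, hi = t.min() - 3 * sd, t.max() + 3 * sd
        nbins = max(20, int(math.sqrt(len(t))))
        dens, edges = np.histogram(t, bins=nbins, range=(lo, hi), density=True)
        # light smoothing so neighbouring empty bins do not zero the density
        kernel = np.array([0.25, 0.5, 0.25])
        dens = np.convolve(dens, kernel, mode="same")
        model._hist_edges = edges
        model._hist_density = dens
    return model


def density(model: InsertSizeModel, t) -> np.ndarray | float:
    """Functional alias for :meth:`InsertSizeModel.density`."""
    return model.density(t)


def shifted_density(model: InsertSizeModel, t, l_alu: float) -> np.ndarray | float:
    """Functional alias for :meth:`InsertSizeModel.shifted_density`."""
    return model.shifted_density(t, l_alu)
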