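"""Consensus Immunoscore determination.

The score is the arithmetic mean of four empirical percentiles — CD3+ and
CD8+ density, each in the center of tumor (CT) and the invasive margin (IM) —
taken against a reference population, binned into pre-defined categories:

* three-level (IS3): Lo [0, 25], Int (25, 70], Hi (70, 100]
* two-level  (IS2): Lo [0, 25], Int+Hi (25, 100]
* five-level (IS5): I0 [0, 10], I1 (10, 25], I2 (25, 70], I3 (70, 95],
  I4 (95, 100]

All interior boundaries are closed on the right and open on the left; a mean
percentile of exactly 25 is Lo under every scheme.  The percentile of a
density is the inclusive fraction of reference values less than or equal to
it, so the transform is a right-continuous step function reaching 100 at the
reference maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .reference import MARKER_REGION_PAIRS, ReferenceDistribution, default_reference
from .quantify import SlideQuantification

IS3_LABELS = ("Lo", "Int", "Hi")
IS2_LABELS = ("Lo", "IntHi")
IS5_LABELS = ("I0", "I1", "I2", "I3", "I4")

#: Right band edges of the five-level scheme; the coarser schemes merge these.
_IS5_EDGES = (10.0, 25.0, 70.0, 95.0, 100.0)
_IS3_EDGES = (25.0, 70.0, 100.0)
_IS2_EDGES = (25.0, 100.0)

#: Column naming used in scored cohort tables.
DENSITY_COLUMNS = {
    ("CD3", "CT"): "cd3_ct",
    ("CD3", "IM"): "cd3_im",
    ("CD8", "CT"): "cd8_ct",
    ("CD8", "IM"): "cd8_im",
}
PERCENTILE_COLUMNS = {k: f"pct_{v}" for k, v in DENSITY_COLUMNS.items()}


def density_to_percentile(
    density: float, marker: str, region: str, ref: ReferenceDistribution
) -> float:
    """Percentile of ``density`` in the (marker, region) reference sequence.

    Defined as 100 x (# reference values <= density) / (reference size).
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    seq = ref[(marker, region)]
    count = int(np.searchsorted(seq, density, side="right"))
    return 100.0 * count / seq.size


def mean_percentile(percentiles) -> float:
    """Arithmetic mean of the four marker/region percentiles."""
    p = np.asarray(percentiles, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"exactly four percentiles required, got shape {p.shape}")
    if np.any(np.isnan(p)):
        raise ValueError(
            "missing percentile: patients with missing region counts must be "
            "excluded by QC before scoring"
        )
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentiles must lie in [0, 100]")
    return float(p.sum() / 4.0)


def _classify_edges(value, edges, labels):
    value = np.asarray(value, dtype=float)
    if np.any((value < 0) | (value > 100)):
        raise ValueError("mean percentile must lie in [0, 100]")
    # interior boundaries: closed right, open left -> index of first edge >= value
    idx = np.searchsorted(np.asarray(edges), value, side="left")
    out = np.asarray(labels, dtype=object)[idx]
    return out if isinstance(out, np.ndarray) else out


def classify(value, scheme: str = "IS3"):
    """Category label(s) for a mean percentile under a given scheme.

    ``value`` may be a scalar or array; returns label(s) accordingly.
    """
    scheme = scheme.upper()
    if scheme == "IS3":
        return _classify_edges(value, _IS3_EDGES, IS3_LABELS)
    if scheme == "IS2":
        return _classify_edges(value, _IS2_EDGES, IS2_LABELS)
    if scheme == "IS5":
        return _classify_edges(value, _IS5_EDGES, IS5_LABELS)
    raise ValueError(f"unknown scheme {scheme!r}; expected IS2, IS3 or IS5")


def coarsen_is5_to_is3(label: str) -> str:
    return {"I0": "Lo", "I1": "Lo", "I2": "Int", "I3": "Hi", "I4": "Hi"}[label]


def coarsen_is3_to_is2(label: str) -> str:
    return {"Lo": "Lo", "Int": "IntHi", "Hi": "IntHi"}[label]


@dataclass(frozen=True)
class ImmunoscoreResult:
    """Percentiles, their mean, and the three category labels for one patient."""

    percentiles: dict
    mean_percentile: float
    is2: str
    is3: str
    is5: str

    def __post_init__(self):
        mp = mean_percentile([self.percentiles[k] for k in MARKER_REGION_PAIRS])
        if abs(mp - self.mean_percentile) > 1e-9:
            raise ValueError("mean_percentile inconsistent with the four percentiles")
        if coarsen_is5_to_is3(self.is5) != self.is3 or coarsen_is3_to_is2(self.is3) != self.is2:
            raise ValueError("category labels are not coarsenings of each other")


class PercentileScorer(BaseEstimator, TransformerMixin):
    """Immunoscore percentile transform as a scikit-learn transformer.

    ``fit`` learns the empirical reference distributions from a table of
    reference densities (columns ``cd3_ct, cd3_im, cd8_ct, cd8_im``), or a
    pre-built :class:`ReferenceDistribution` can be supplied directly via
    :meth:`from_reference`.  ``transform`` appends percentile, mean-percentile
    and IS2/IS3/IS5 label columns; ``predict`` returns labels under ``scheme``.

    Parameters
    ----------
    scheme : {"IS3", "IS2", "IS5"}, default "IS3"
        Scheme returned by :meth:`predict`.

    Attributes
    ----------
    reference_ : ReferenceDistribution
        The fitted reference sequences.
    """

    def __init__(self, scheme: str = "IS3"):
        self.scheme = scheme

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        entries = {}
        for key, col in DENSITY_COLUMNS.items():
            if col not in X.columns:
                raise ValueError(f"reference table lacks density column {col!r}")
            values = np.sort(np.asarray(X[col], dtype=float))
            entries[key] = values
        self.reference_ = ReferenceDistribution(
            entries=entries, provenance={"source": "fitted from table", "n": len(X)}
        )
        return self

    @classmethod
    def from_reference(cls, ref: ReferenceDistribution | None = None, scheme: str = "IS3"):
        """Build an already-fitted scorer around a reference distribution."""
        est = cls(scheme=scheme)
        est.reference_ = ref if ref is not None else default_reference()
        return est

    def _check_fitted(self):
        if not hasattr(self, "reference_"):
            raise RuntimeError("PercentileScorer is not fitted; call fit or from_reference")

    # -- transform ---------------------------------------------------------
    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return ``X`` with percentile, mean and category columns appended."""
        self._check_fitted()
        out = X.copy()
        pct = np.empty((len(X), 4))
        for j, (key, col) in enumerate(DENSITY_COLUMNS.items()):
            dens = np.asarray(X[col], dtype=float)
            if np.any(dens < 0):
                raise ValueError(f"negative density in column {col!r}")
            seq = self.reference_[key]
            pct[:, j] = 100.0 * np.searchsorted(seq, dens, side="right") / seq.size
            out[PERCENTILE_COLUMNS[key]] = pct[:, j]
        mean = pct.sum(axis=1) / 4.0
        out["mean_percentile"] = mean
        out["is2"] = classify(mean, "IS2")
        out["is3"] = classify(mean, "IS3")
        out["is5"] = classify(mean, "IS5")
        return out

    def predict(self, X: pd.DataFrame):
        """Category labels under ``self.scheme`` for a density table."""
        return np.asarray(self.transform(X)[self.scheme.lower()])


def score_patient(q: SlideQuantification, ref: ReferenceDistribution) -> ImmunoscoreResult:
    """Score one QC-passed slide quantification against a reference."""
    if not q.qc_pass:
        raise ValueError(
            f"patient {q.patient_id!r} failed QC ({', '.join(q.qc_reasons)}) and is "
            "excluded from scoring"
        )
    percentiles = {
        key: density_to_percentile(q.density[key], key[0], key[1], ref)
        for key in MARKER_REGION_PAIRS
    }
    mp = mean_percentile([percentiles[k] for k in MARKER_REGION_PAIRS])
    return ImmunoscoreResult(
        percentiles=percentiles,
        mean_percentile=mp,
        is2=classify(mp, "IS2"),
        is3=classify(mp, "IS3"),
        is5=classify(mp, "IS5"),
    )


def score_cohort(
    cohort: pd.DataFrame, ref: ReferenceDistribution | None = None
) -> pd.DataFrame:
    """Append percentiles, mean percentile and IS2/IS3/IS5 labels to a cohort table."""
    scorer = PercentileScorer.from_reference(ref)
    return scorer.transform(cohort)
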