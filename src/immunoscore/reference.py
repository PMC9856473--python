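"""Reference density distributions underlying the percentile transform.

The Immunoscore converts a patient's CD3+ and CD8+ cell densities, measured
in the center of tumor (CT) and the invasive margin (IM), into percentiles of
a pre-computed reference population of densities.  The consensus reference
itself is not public, so this module provides a synthetic stand-in: four
ordered density sequences (marker x region), generated reproducibly from a
seed, against which the forward and inverse percentile transforms operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

MARKERS = ("CD3", "CD8")
REGIONS = ("CT", "IM")
MARKER_REGION_PAIRS = tuple((m, r) for m in MARKERS for r in REGIONS)

#: Seed of the packaged default reference (see :func:`default_reference`).
DEFAULT_REFERENCE_SEED = 20230108

#: Log-normal location/scale per (marker, region) for the default reference.
#: Medians are plausible T-cell densities (cells/mm^2) for colon tumors:
#: CD3 denser than CD8, the invasive margin denser than the tumor center.
DEFAULT_REFERENCE_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("CD3", "CT"): (np.log(500.0), 1.0),
    ("CD3", "IM"): (np.log(800.0), 0.9),
    ("CD8", "CT"): (np.log(150.0), 1.1),
    ("CD8", "IM"): (np.log(350.0), 1.0),
}


@dataclass(frozen=True)
class ReferenceDistribution:
    """Ordered reference density sequences, one per (marker, region).

    Parameters
    ----------
    entries : mapping of (marker, region) -> 1-D ndarray
        Sorted ascending, non-negative densities in cells/mm^2, length >= 100.
    provenance : dict
        Seed and generation parameters, for reproducibility bookkeeping.
    """

    entries: Mapping[tuple[str, str], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        frozen: dict[tuple[str, str], np.ndarray] = {}
        for key, values in self.entries.items():
            arr = np.array(values, dtype=float)  # defensive copy
            if arr.ndim != 1 or arr.size < 100:
                raise ValueError(
                    f"reference sequence for {key} must be 1-D with length >= 100"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"reference densities for {key} must be finite and >= 0")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"reference sequence for {key} must be sorted ascending")
            arr.setflags(write=False)
            frozen[key] = arr
        object.__setattr__(self, "entries", frozen)

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(f"no reference sequence for marker/region {key!r}") from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def size(self, marker: str, region: str) -> int:
        return int(self[(marker, region)].size)


def generate_reference(
    params: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    *,
    family: str = "lognormal",
    size: int = 1000,
    seed: int,
) -> ReferenceDistribution:
    """Generate a synthetic reference distribution.

    Parameters
    ----------
    params : mapping of (marker, region) -> (loc, scale)
        For ``family="lognormal"``: mean and SD of log-density.
        For ``family="degenerate"``: (value, ignored) — all mass at one point.
    family : {"lognormal", "degenerate"}
    size : int
        Sequence length per (marker, region); must be >= 100.
    seed : int
        Deterministic: identical seed reproduces the sequences bit-for-bit.
    """
    if params is None:
        params = DEFAULT_REFERENCE_PARAMS
    if size < 100:
        raise ValueError(f"reference size must be >= 100, got {size}")
    rng = np.random.default_rng(seed)
    entries: dict[tuple[str, str], np.ndarray] = {}
    for key in sorted(params):  # fixed iteration order -> seed determinism
        loc, scale = params[key]
        if family == "lognormal":
            if scale <= 0:
                raise ValueError(f"scale for {key} must be > 0, got {scale}")
            values = rng.lognormal(mean=loc, sigma=scale, size=size)
        elif family == "degenerate":
            if loc < 0:
                raise ValueError(f"degenerate density must be >= 0, got {loc}")
            values = np.full(size, float(loc))
        else:
            raise ValueError(f"unknown reference family {family!r}")
        entries[key] = np.sort(values)
    provenance = {
        "seed": seed,
        "family": family,
        "size": size,
        "params": {f"{m}_{r}": list(map(float, v)) for (m, r), v in params.items()},
    }
    return ReferenceDistribution(entries=entries, provenance=provenance)


def default_reference() -> ReferenceDistribution:
    """The packaged default reference (fixed seed, log-normal, n=1000 per pair).

    A deterministic stand-in for the unpublished consensus reference: calling
    this repeatedly, on any machine, yields bit-identical sequences.
    """
    return generate_reference(
        DEFAULT_REFERENCE_PARAMS, family="lognormal", size=1000, seed=DEFAULT_REFERENCE_SEED
    )


def representable_percentile(
    percentile: float, marker: str, region: str, ref: ReferenceDistribution
) -> float:
    """Snap a percentile to the nearest value exactly representable by ``ref``.

    The forward transform takes values on the grid {100*k/n : k=0..n}; the
    returned value is the grid point closest to ``percentile``.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    n = ref.size(marker, region)
    k = int(round(percentile * n / 100.0))
    return 100.0 * k / n


def inverse_percentile_density(
    percentile: float, marker: str, region: str, ref: ReferenceDistribution
) -> float:
    """Right inverse of the density->percentile transform.

    Returns a density whose forward percentile reproduces ``percentile`` to
    within the granularity of the reference (<= 100/len percentile points).
    Percentile 0 maps to a value strictly below the reference minimum;
    percentile 100 maps to the reference maximum.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    seq = ref[(marker, region)]
    n = seq.size
    k = int(round(percentile * n / 100.0))
    if k == 0:
        lo = float(seq[0])
        if lo <= 0.0:
            raise ValueError(
                "percentile 0 is not representable: the reference minimum is 0 "
                "and densities cannot be negative"
            )
        return 0.5 * lo
    return float(seq[k - 1])
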