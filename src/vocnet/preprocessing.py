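"""Per-VOC descriptive statistics and the binarization schemes.

Emission series are heavy-tailed: mostly zeros, a low plateau, and rare
large spikes.  Boxplot machinery (quartiles, IQR, Tukey fences) describes
each VOC's distribution across species; binarization turns the real-valued
matrix into the binary species × VOC incidence matrix that defines the
bipartite graph.  Two schemes are supported:

* ``fixed`` — emission counts iff strictly above a fixed intensity
  (1 ncps for the dense graph; 0 ncps to separate any emission from none);
* ``q3`` — per VOC, only emissions strictly above that VOC's third
  quartile across species count (a much more severe pruning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EmissionMatrix

__all__ = [
    "quartiles",
    "boxplot_stats",
    "standardize",
    "BoxplotSummary",
    "IncidenceMatrix",
    "binarize_fixed",
    "binarize_third_quartile",
    "select_vocs",
]


def quartiles(values, method: str = "linear") -> tuple[float, float, float]:
    """Quartiles (Q1, Q2, Q3) of a series.

    ``method="linear"`` is linear interpolation between order statistics
    (quantile type 7, the common default); ``method="hinges"`` uses Tukey's
    hinges (medians of the lower/upper half, including the overall median
    when n is odd) to probe sensitivity of downstream thresholds.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("quartiles of an empty series are undefined")
    if not np.isfinite(x).all():
        raise ValueError("quartiles require finite values")
    if method == "linear":
        q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75], method="linear")
    elif method == "hinges":
        s = np.sort(x)
        n = s.size
        q2 = float(np.median(s))
        half = (n + 1) // 2  # halves share the middle point when n is odd
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    return float(q1), float(q2), float(q3)


@dataclass
class BoxplotSummary:
    """Boxplot statistics of one VOC's emissions across species.

    Outliers lie outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; extreme events lie
    outside [Q1 − 3·IQR, Q3 + 3·IQR].  Index sets refer to positions in the
    input series.
    """

    q1: float
    q2: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    lower_extreme: float
    upper_extreme: float
    outlier_idx: set[int] = field(default_factory=set)
    extreme_idx: set[int] = field(default_factory=set)


def boxplot_stats(values, method: str = "linear") -> BoxplotSummary:
    """Quartiles, Tukey fences, and outlier/extreme index sets."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("boxplot statistics need at least 4 values")
    q1, q2, q3 = quartiles(x, method=method)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_e, hi_e = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    outliers = {int(i) for i in np.nonzero((x < lo_f) | (x > hi_f))[0]}
    extremes = {int(i) for i in np.nonzero((x < lo_e) | (x > hi_e))[0]}
    return BoxplotSummary(q1, q2, q3, iqr, lo_f, hi_f, lo_e, hi_e, outliers, extremes)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to unit sample (n−1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant series (zero variance)")
    return (x - x.mean()) / sd


@dataclass
class IncidenceMatrix:
    """Binary species × VOC matrix defining the bipartite graph.

    ``scheme`` records the thresholding rule so the bits are reproducible
    from the source emission matrix:
    ``{"rule": "fixed"|"q3", "threshold": float|None,
    "quantile_type": "linear"|"hinges"}``.
    """

    species_ids: list[str]
    voc_ids: list[str]
    bits: np.ndarray
    scheme: dict

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.species_ids), len(self.voc_ids)):
            raise ValueError("incidence shape does not match label lists")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")

    @property
    def n_ones(self) -> int:
        return int(self.bits.sum())


def binarize_fixed(matrix: EmissionMatrix, threshold: float) -> IncidenceMatrix:
    """Mark cells with emission strictly above a fixed ncps threshold.

    ``threshold=1`` reproduces the dense-graph rule; ``threshold=0``
    separates relevant from negligible emission (any signal counts).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0 ncps")
    bits = (matrix.values > threshold).astype(np.int8)
    scheme = {"rule": "fixed", "threshold": float(threshold), "quantile_type": None}
    return IncidenceMatrix(matrix.species_ids, matrix.voc_ids, bits, scheme)


def binarize_third_quartile(matrix: EmissionMatrix, method: str = "linear") -> IncidenceMatrix:
    """Mark, per VOC column, cells strictly above that column's Q3.

    Each VOC's quartile is computed across all species (zeros included), so
    a column that is ≥ 75% zeros can only have its nonzero spikes marked,
    and an all-zero column is marked nowhere.
    """
    if matrix.n_species < 4:
        raise ValueError("third-quartile binarization needs >= 4 species")
    vals = matrix.values
    q3 = np.array([quartiles(vals[:, j], method=method)[2] for j in range(vals.shape[1])])
    bits = (vals > q3[np.newaxis, :]).astype(np.int8)
    scheme = {"rule": "q3", "threshold": None, "quantile_type": method}
    return IncidenceMatrix(matrix.species_ids, matrix.voc_ids, bits, scheme)


def select_vocs(matrix: EmissionMatrix, keep: list[str]) -> EmissionMatrix:
    """Column-subset the matrix to a chosen VOC panel (species unchanged).

    Used to drop wounding-associated and weakly aggregating channels before
    building the reduced-panel graph; the panel is configuration, not code.
    """
    unknown = [v for v in keep if v not in matrix.data.columns]
    if unknown:
        raise KeyError(f"unknown VOC label(s): {unknown}")
    sub = matrix.data.loc[:, list(keep)]
    chem = {v: c for v, c in matrix.chem_class_of.items() if v in keep}
    return EmissionMatrix(sub, family_of=dict(matrix.family_of), chem_class_of=chem)
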