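"""Connectivity preprocessing: from raw tracer weights to model-ready matrices.

Matrix orientation is row = target area i, column = source area j throughout
the package: ``W[i, j]`` is the strength of the projection from j to i. The
staged pipeline is

1. volume/density normalization  ``W_norm[i,j] = W_raw[i,j] * Vol_j / d_i``
2. hierarchy completion (weighted-sum imputation) and min-max normalization
   of hierarchy and PV fraction over cortical areas
3. power-law compression and max-normalization
   ``W = W_norm**k_scale / max(W_norm**k_scale)``
4. counterstream-inhibitory-bias (CIB) split into excitatory- and
   inhibitory-targeting components ``W_E = m * W``, ``W_I = (1-m) * W`` with
   ``m[i,j] = sigmoid(beta * (h_i - h_j))``
5. cell type-specific variants used by the graph measures.

Self-projections are not modeled: diagonals are forced to zero on load.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AreaAtlas
from .params import ModelParams

__all__ = [
    "normalize_connectivity",
    "minmax_normalize",
    "impute_hierarchy",
    "rescale_connectivity",
    "cib_matrix",
    "split_by_target",
    "celltype_matrix",
    "Connectome",
    "build_connectome",
    "read_weight_csv",
    "write_weight_csv",
]


def _check_square(W: np.ndarray, n: int | None = None) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got shape {W.shape}")
    if n is not None and W.shape[0] != n:
        raise ValueError(f"weight matrix has {W.shape[0]} areas, atlas has {n}")
    return W


def zero_diagonal(W: np.ndarray) -> np.ndarray:
    W = np.array(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    return W


def normalize_connectivity(W_raw: np.ndarray, atlas: AreaAtlas) -> np.ndarray:
    """Per-neuron normalization ``W_norm[i,j] = W_raw[i,j] * Vol_j / d_i``.

    Raw tracer weights are proportional to fibers per unit source volume;
    multiplying by the source volume and dividing by the target neuron
    density converts them to input per average target neuron.
    """
    W_raw = _check_square(W_raw, len(atlas))
    vol = atlas.volumes
    dens = atlas.neuron_density
    for label, v in (("volume", vol), ("neuron density", dens)):
        if (~np.isfinite(v)).any() or (v <= 0).any():
            bad = [n for n, ok in zip(atlas.names, np.isfinite(v) & (v > 0)) if not ok]
            raise ValueError(f"invalid {label} for areas: {bad}")
    return W_raw * vol[None, :] / dens[:, None]


def minmax_normalize(values, bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max normalize to [0, 1]; NaN entries pass through untouched.

    ``bounds`` supplies an explicit (min, max) — used to place thalamic
    hierarchy scores on the cortical scale, in which case results may fall
    outside [0, 1].
    """
    values = np.asarray(values, dtype=float)
    present = values[np.isfinite(values)]
    if bounds is None:
        if present.size < 2:
            raise ValueError("need at least two present values to normalize")
        lo, hi = present.min(), present.max()
    else:
        lo, hi = bounds
    if hi <= lo:
        raise ValueError("zero range: max must exceed min")
    return (values - lo) / (hi - lo)


def impute_hierarchy(W_raw: np.ndarray, h_known: np.ndarray,
                     alpha_h: float = 1.33, beta_h: float = -0.22) -> np.ndarray:
    """Fill missing hierarchy scores from connectivity-weighted neighbors.

    For each area i with missing hierarchy,
    ``h_i = alpha_h * (sum_j W_raw[i,j] h_j / sum_j W_raw[i,j]) + beta_h``
    where the sums run over areas with known hierarchy. Known entries are
    returned untouched.
    """
    W_raw = _check_square(W_raw)
    h = np.array(h_known, dtype=float)
    known = np.isfinite(h)
    if known.all():
        return h
    for i in np.flatnonzero(~known):
        w = W_raw[i, known]
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"area index {i} has no input from areas with known hierarchy")
        h[i] = alpha_h * float(w @ h[known]) / total + beta_h
    return h


def refit_hierarchy_coeffs(W_raw: np.ndarray, h_known: np.ndarray) -> tuple[float, float]:
    """Least-squares refit of the imputation coefficients (alpha_h, beta_h).

    Regresses the known hierarchy values on their own connectivity-weighted
    neighbor means. Optional; the printed defaults are used unless a caller
    asks for a refit.
    """
    W_raw = _check_square(W_raw)
    h = np.asarray(h_known, dtype=float)
    known = np.isfinite(h)
    if known.sum() < 3:
        raise ValueError("need at least three known hierarchy values to refit")
    idx = np.flatnonzero(known)
    x = []
    for i in idx:
        others = known.copy()
        others[i] = False
        w = W_raw[i, others]
        if w.sum() <= 0:
            raise ValueError(f"area index {i} has no weighted neighbors")
        x.append(float(w @ h[others]) / w.sum())
    A = np.column_stack([x, np.ones(len(x))])
    coef, *_ = np.linalg.lstsq(A, h[idx], rcond=None)
    return float(coef[0]), float(coef[1])


def rescale_connectivity(W_norm: np.ndarray, k_scale: float = 0.3) -> np.ndarray:
    """Compress the dynamic range: ``W = W_norm**k / max(W_norm**k)``.

    Tracer weights span several orders of magnitude; the power law with
    ``k_scale < 1`` compresses that range while preserving the ordering of
    entries. The result is max-normalized to exactly 1.
    """
    W_norm = _check_square(W_norm)
    if not (0 < k_scale <= 1):
        raise ValueError("k_scale must lie in (0, 1]")
    if (W_norm < 0).any():
        raise ValueError("weights must be nonnegative")
    W = np.power(W_norm, k_scale, where=W_norm > 0, out=np.zeros_like(W_norm))
    peak = W.max()
    if peak <= 0:
        raise ValueError("cannot rescale an all-zero matrix")
    return W / peak


def cib_matrix(h: np.ndarray, beta: float = 2.42, h_source: np.ndarray | None = None) -> np.ndarray:
    """Counterstream-inhibitory-bias coefficients.

    ``m[i,j] = 1 / (1 + exp(-beta * (h_i - h_j)))`` measures the
    feedforwardness of the projection from source j to target i: climbing
    the hierarchy gives m > 0.5 (biased onto excitatory targets), descending
    gives m < 0.5 (biased onto inhibitory targets). ``h_source`` allows a
    different source hierarchy vector (cortico-thalamic coupling); by
    default source and target share ``h`` and ``m + m.T == 1``.
    """
    h = np.asarray(h, dtype=float)
    hs = h if h_source is None else np.asarray(h_source, dtype=float)
    diff = h[:, None] - hs[None, :]
    return 1.0 / (1.0 + np.exp(-beta * diff))


def split_by_target(W: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split total weights into E-targeting and I-targeting components.

    ``W_E = m * W`` and ``W_I = (1 - m) * W``; their sum reproduces W
    exactly.
    """
    W = np.asarray(W, dtype=float)
    m = np.asarray(m, dtype=float)
    if W.shape != m.shape:
        raise ValueError("W and m must have the same shape")
    W_E = m * W
    return W_E, W - W_E


def celltype_matrix(W: np.ndarray, m: np.ndarray, PV: np.ndarray,
                    mode: str = "celltype") -> np.ndarray:
    """Cell type-aware connectivity variants used by the graph measures.

    ``celltype``:  ``(m[i,j] - PV_i*(1-m[i,j])) * W[i,j]``, max-normalized —
    an edge counts positively insofar as it targets excitatory cells, and is
    discounted by the target area's PV fraction for its inhibitory component.
    ``sign_only``: ``sgn(2m-1) * W`` (feedback edges flip sign, magnitudes kept).
    ``noPV``:      ``(2m-1) * W`` (graded hierarchy bias, no PV discount).
    Entries may be negative in every mode; only ``celltype`` is normalized.
    """
    W = np.asarray(W, dtype=float)
    m = np.asarray(m, dtype=float)
    if mode == "celltype":
        PV = np.asarray(PV, dtype=float)
        k_cell = m - PV[:, None] * (1.0 - m)
        W_cell = k_cell * W
        peak = W_cell.max()
        if peak <= 0:
            raise ValueError("degenerate celltype normalization: max(W_cell) <= 0")
        return W_cell / peak
    if mode == "sign_only":
        return np.sign(2.0 * m - 1.0) * W
    if mode == "noPV":
        return (2.0 * m - 1.0) * W
    raise ValueError(f"unknown variant {mode!r}")


# ---------------------------------------------------------------------------


@dataclass
class Connectome:
    """Staged connectivity matrices plus the normalized area gradients.

    All matrices are target-by-source with zero diagonals. ``W`` is the
    simulation matrix (max exactly 1), ``W_E``/``W_I`` its CIB split, and
    ``variants`` maps {'celltype', 'sign_only', 'noPV'} to the graph-measure
    matrices.
    """

    atlas: AreaAtlas
    W_raw: np.ndarray
    W_norm: np.ndarray
    W: np.ndarray
    h: np.ndarray            # normalized hierarchy, min 0 / max 1
    PV: np.ndarray           # normalized PV fraction, min 0 / max 1
    m: np.ndarray            # CIB coefficients
    W_E: np.ndarray
    W_I: np.ndarray
    variants: dict = field(default_factory=dict)

    @property
    def n_areas(self) -> int:
        return len(self.atlas)

    @property
    def names(self) -> list[str]:
        return self.atlas.names

    def variant(self, name: str) -> np.ndarray:
        if name == "raw":
            return self.W
        if name not in ("celltype", "sign_only", "noPV"):
            raise KeyError(f"unknown connectivity variant {name!r}")
        if name not in self.variants:
            self.variants[name] = celltype_matrix(self.W, self.m, self.PV, name)
        return self.variants[name]

    def with_mean_cib(self) -> "Connectome":
        """Control connectome with the CIB replaced by its mean (m = 0.5)."""
        m = np.full_like(self.m, 0.5)
        W_E, W_I = split_by_target(self.W, m)
        return dataclasses.replace(self, m=m, W_E=W_E, W_I=W_I)

    def validate(self, atol: float = 1e-12) -> None:
        """Check the staged-matrix invariants; raise AssertionError on failure."""
        for name in ("W_raw", "W_norm", "W"):
            M = getattr(self, name)
            assert (M >= 0).all(), f"{name} has negative entries"
            assert np.abs(np.diag(M)).max() == 0, f"{name} diagonal not zero"
        assert abs(self.W.max() - 1.0) <= atol, "W is not max-normalized"
        assert np.allclose(self.W_E + self.W_I, self.W, atol=atol)
        assert ((self.m > 0) & (self.m < 1)).all()
        assert abs(self.PV.min()) <= atol and abs(self.PV.max() - 1.0) <= atol
        assert abs(self.h.min()) <= atol and abs(self.h.max() - 1.0) <= atol


def build_connectome(atlas: AreaAtlas, W_raw: np.ndarray,
                     params: ModelParams | None = None,
                     impute: bool = True) -> Connectome:
    """Run the full preprocessing pipeline on a cortical atlas + raw weights.

    The atlas must be cortex-only (thalamic coupling is handled by
    :mod:`distwm.thalamus`). Missing hierarchy scores are imputed from the
    raw weights before normalization unless ``impute=False``.
    """
    params = params or ModelParams()
    if atlas.is_thalamic.any():
        raise ValueError("build_connectome expects a cortex-only atlas; "
                         "use the thalamocortical builder for thalamic areas")
    W_raw = zero_diagonal(_check_square(W_raw, len(atlas)))
    if (W_raw < 0).any():
        raise ValueError("raw weights must be nonnegative")
    W_norm = normalize_connectivity(W_raw, atlas)

    h_raw = atlas.hierarchy_raw
    if impute:
        h_raw = impute_hierarchy(W_raw, h_raw, params.alpha_h, params.beta_h)
    elif not np.isfinite(h_raw).all():
        raise ValueError("hierarchy has gaps and imputation is disabled")
    h = minmax_normalize(h_raw)
    PV = minmax_normalize(atlas.pv_fraction_raw)

    W = rescale_connectivity(W_norm, params.k_scale)
    m = cib_matrix(h, params.beta)
    W_E, W_I = split_by_target(W, m)
    variants = {
        "celltype": celltype_matrix(W, m, PV, "celltype"),
        "sign_only": celltype_matrix(W, m, PV, "sign_only"),
        "noPV": celltype_matrix(W, m, PV, "noPV"),
    }
    conn = Connectome(atlas=atlas, W_raw=W_raw, W_norm=W_norm, W=W, h=h, PV=PV,
                      m=m, W_E=W_E, W_I=W_I, variants=variants)
    conn.validate()
    return conn


# -- CSV dialect ------------------------------------------------------------

def read_weight_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a weight matrix CSV (first row/column = area names).

    Returns ``(matrix, names)``; orientation is target rows by source
    columns, as recorded in the sidecar metadata written by
    :func:`write_weight_csv`.
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("weight CSV row and column names disagree")
    return df.to_numpy(float), list(df.index)


def write_weight_csv(path, W: np.ndarray, names: list[str],
                     stage: str = "raw", units: str = "a.u.") -> None:
    """Write a weight matrix CSV plus a sidecar JSON metadata file."""
    pd.DataFrame(W, index=names, columns=names).to_csv(path)
    meta = {"orientation": "row=target,column=source", "stage": stage, "units": units}
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
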