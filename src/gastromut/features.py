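"""The 150-dimensional handcrafted sequence descriptor.

A nucleotide sequence is summarised by six feature blocks, concatenated in a
fixed layout:

=====================  ======  =======================================================
block                  width   content
=====================  ======  =======================================================
sequence-matrix moments  30    10 raw + 10 central + 10 Hahn moments of the k x k
                               row-major square matrix holding the encoded sequence
PRIM moments             30    same 30 moments of the position-relative incidence
                               matrix (K x K)
RPRIM moments            30    same, for the reverse sequence
FDV                      K*    per-symbol occurrence counts
AAPIV                    K*    per-symbol sums of 1-based occurrence positions
RAAPIV                   K*    AAPIV of the reversed sequence
=====================  ======  =======================================================

In the canonical "full" mode the alphabet capacity is K = 20 — A, C, G, T
occupy ordinals 1-4 and slots 5-20 are structural zero-padding — giving a
150-value vector and 400 PRIM coefficients.  "compact" mode sets K = 4
(102 values).  Moments are taken up to combined order three: ten (i, j)
pairs per kind.  'N' bases are dropped before encoding.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, ValidationError
from .hahn import MOMENT_ORDERS, hahn_moments

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
FULL_K = 20
COMPACT_K = 4


@dataclass(frozen=True)
class FeatureConfig:
    """Mode and Hahn shape parameters of the descriptor."""

    mode: str = "full"  # "full" (K=20, 150-D) or "compact" (K=4, 102-D)
    u: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "compact"):
            raise ConfigurationError(f"unknown feature mode {self.mode!r}")

    @property
    def K(self) -> int:
        return FULL_K if self.mode == "full" else COMPACT_K

    @property
    def n_features(self) -> int:
        return 90 + 3 * self.K


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to ordinals A=1, C=2, G=3, T=4, dropping N positions."""
    seq = sequence.upper()
    bad = set(seq) - set(NUCLEOTIDES + "N")
    if bad:
        raise ValidationError(f"illegal symbols {sorted(bad)} in sequence")
    dropped = seq.count("N")
    if dropped:
        logger.debug("dropped %d ambiguous (N) positions", dropped)
        seq = seq.replace("N", "")
    if not seq:
        raise DegenerateInputError("sequence contains no unambiguous bases")
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(NUCLEOTIDES, start=1):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def reshape_to_square(series: np.ndarray) -> np.ndarray:
    """Pack an ordinal series into the smallest k x k matrix, row-major.

    k = ceil(sqrt(n)); trailing cells are zero padding.
    """
    series = np.asarray(series, dtype=np.int64)
    n = series.size
    if n < 1:
        raise DegenerateInputError("cannot reshape an empty series")
    k = math.isqrt(n - 1) + 1  # ceil(sqrt(n)) for integer n >= 1
    cells = np.zeros(k * k, dtype=np.int64)
    cells[:n] = series
    return cells.reshape(k, k)


def raw_moments(matrix: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Ten raw moments W_ij = sum b^i q^j m(b, q) with 1-based indices, plus centroid."""
    m = np.asarray(matrix, dtype=float)
    if not np.any(m):
        raise DegenerateInputError("all-zero matrix has no moments")
    b = np.arange(1, m.shape[0] + 1, dtype=float)[:, None]
    q = np.arange(1, m.shape[1] + 1, dtype=float)[None, :]
    w = np.array([np.sum(b**i * q**j * m) for (i, j) in MOMENT_ORDERS])
    w00 = w[MOMENT_ORDERS.index((0, 0))]
    w10 = w[MOMENT_ORDERS.index((1, 0))]
    w01 = w[MOMENT_ORDERS.index((0, 1))]
    centroid = (w10 / w00, w01 / w00)
    return w, centroid


def central_moments(matrix: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """Ten central moments Q_ij about the centroid (Q10 = Q01 = 0 by construction)."""
    m = np.asarray(matrix, dtype=float)
    xbar, ybar = centroid
    b = np.arange(1, m.shape[0] + 1, dtype=float)[:, None]
    q = np.arange(1, m.shape[1] + 1, dtype=float)[None, :]
    return np.array([np.sum((b - xbar) ** i * (q - ybar) ** j * m) for (i, j) in MOMENT_ORDERS])


def moment_block(matrix: np.ndarray, u: float = 0.0, v: float = 0.0) -> np.ndarray:
    """The 30-value block [10 raw, 10 central, 10 Hahn] of a square matrix."""
    w, centroid = raw_moments(matrix)
    q = central_moments(matrix, centroid)
    h = hahn_moments(matrix, u, v)
    return np.concatenate([w, q, h])


def _first_occurrence(series: np.ndarray, K: int) -> np.ndarray:
    """1-based first-occurrence position per ordinal (0 = absent)."""
    first = np.zeros(K + 1, dtype=np.int64)
    for p, s in enumerate(series, start=1):
        if first[s] == 0:
            first[s] = p
    return first


def prim(sequence: str | np.ndarray, K: int = FULL_K) -> np.ndarray:
    """Position-relative incidence matrix.

    cell(i, j) accumulates, over every occurrence of symbol j strictly after
    the first occurrence of symbol i, the positional offset from that first
    occurrence: cell(i, j) = sum_{p in pos(j), p > f_i} (p - f_i).  Rows of
    absent symbols stay zero.
    """
    series = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    if series.size == 0:
        raise DegenerateInputError("empty series")
    first = _first_occurrence(series, K)
    positions = np.arange(1, series.size + 1, dtype=np.int64)
    out = np.zeros((K, K), dtype=np.int64)
    for i in range(1, K + 1):
        f = first[i]
        if f == 0:
            continue
        later = positions > f
        if not np.any(later):
            continue
        offsets = positions[later] - f
        sym = series[later]
        for j in range(1, K + 1):
            out[i - 1, j - 1] = offsets[sym == j].sum()
    return out


def rprim(sequence: str | np.ndarray, K: int = FULL_K) -> np.ndarray:
    """PRIM of the reversed sequence."""
    series = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    return prim(series[::-1], K)


def fdv(sequence: str | np.ndarray, K: int = FULL_K) -> np.ndarray:
    """Frequency distribution vector: slot i = occurrence count of symbol i."""
    series = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    return np.bincount(series, minlength=K + 1)[1 : K + 1].astype(np.int64)


def aapiv(sequence: str | np.ndarray, K: int = FULL_K) -> np.ndarray:
    """Accumulative absolute position incidence vector.

    Slot i = sum of the 1-based positions at which symbol i occurs.
    """
    series = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    positions = np.arange(1, series.size + 1, dtype=np.int64)
    return np.bincount(series, weights=positions, minlength=K + 1)[1 : K + 1].astype(np.int64)


def raapiv(sequence: str | np.ndarray, K: int = FULL_K) -> np.ndarray:
    """AAPIV of the reversed sequence."""
    series = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    return aapiv(series[::-1], K)


def assemble_features(sequence: str, config: FeatureConfig | None = None) -> np.ndarray:
    """The full ordered descriptor of one sequence (150 values in full mode)."""
    cfg = config or FeatureConfig()
    series = encode(sequence)
    K, u, v = cfg.K, cfg.u, cfg.v
    blocks = [
        moment_block(reshape_to_square(series), u, v),
        moment_block(prim(series, K), u, v),
        moment_block(rprim(series, K), u, v),
        fdv(series, K).astype(float),
        aapiv(series, K).astype(float),
        raapiv(series, K).astype(float),
    ]
    vec = np.concatenate(blocks)
    assert vec.size == cfg.n_features
    return vec


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Ordered column names matching :func:`assemble_features`."""
    cfg = config or FeatureConfig()
    names: list[str] = []
    for block in ("seq", "prim", "rprim"):
        for kind in ("W", "Q", "H"):
            names += [f"{block}_{kind}{i}{j}" for (i, j) in MOMENT_ORDERS]
    slots = list(NUCLEOTIDES) + [f"pad{i:02d}" for i in range(5, cfg.K + 1)]
    for block in ("fdv", "aapiv", "raapiv"):
        names += [f"{block}_{s}" for s in slots]
    return names


def extract_table(
    sequences: Iterable, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Feature table for a labelled corpus: one row per sequence.

    Accepts an iterable of :class:`~gastromut.corpus.LabeledSequence` (or any
    object with ``sample_id``, ``sequence``, ``label``).  Columns are the
    ordered feature names plus ``label``; the index is the sample id.
    """
    cfg = config or FeatureConfig()
    ids, rows, labels = [], [], []
    for s in sequences:
        ids.append(s.sample_id)
        rows.append(assemble_features(s.sequence, cfg))
        labels.append(s.label)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=feature_names(cfg))
    df["label"] = labels
    return df


def write_feature_table(
    df: pd.DataFrame,
    path: str | Path,
    config: FeatureConfig | None = None,
    provenance: str | None = None,
) -> None:
    """Write the table as CSV plus a sidecar JSON layout descriptor.

    ``provenance`` is an optional ``#``-prefixed comment line recorded at the
    top of the CSV (ignored on reload).
    """
    cfg = config or FeatureConfig()
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance if provenance.endswith("\n") else provenance + "\n")
        df.to_csv(fh)
    layout = {
        "mode": cfg.mode,
        "u": cfg.u,
        "v": cfg.v,
        "n_features": cfg.n_features,
        "columns": feature_names(cfg),
    }
    path.with_suffix(".layout.json").write_text(json.dumps(layout, indent=1))


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, FeatureConfig]:
    """Reload a feature table and its layout; verifies the column order."""
    path = Path(path)
    layout = json.loads(path.with_suffix(".layout.json").read_text())
    cfg = FeatureConfig(mode=layout["mode"], u=layout["u"], v=layout["v"])
    df = pd.read_csv(path, index_col="sample_id", comment="#")
    expected = layout["columns"] + ["label"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: column layout does not match sidecar descriptor")
    return df, cfg
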