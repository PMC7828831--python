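"""Tamura 3-parameter (T92) distances and outgroup-calibrated divergence.

The T92 model extends Kimura's two-parameter model with a GC-content bias
theta.  With P and Q the observed proportions of transition and transversion
differences and h = 2*theta*(1-theta), the distance is

    d = -h * ln(1 - P/h - Q) - (1/2) * (1 - h) * ln(1 - 2Q)

which reduces to the Kimura 2-parameter estimator at theta = 1/2.  Standard
errors come from bootstrap resampling of sites; divergence times are
obtained by scaling an independently dated outgroup split:
t = t_outgroup * d_ingroup / mean(d_outgroups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """The observed divergence is outside the domain of the T92 estimator."""


@dataclass(frozen=True)
class DistanceResult:
    """T92 distance between two aligned sequences.

    P, Q: transition/transversion difference proportions; theta: pooled GC
    content of the compared columns; h = 2*theta*(1-theta); d: distance in
    substitutions per site; se: bootstrap standard error if computed;
    n_sites: number of pairwise-complete columns compared.
    """

    P: float
    Q: float
    theta: float
    h: float
    d: float
    n_sites: int
    se: float | None = None


def _encode_pair(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_set = np.frombuffer(b"ACGT", dtype="S1")
    mask = np.isin(a, valid_set) & np.isin(b, valid_set)
    return a[mask], b[mask]


def _column_classes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (difference class, GC base count) with class 0 identical,
    1 transition, 2 transversion."""
    purine = np.isin(a, np.frombuffer(b"AG", dtype="S1"))
    purine_b = np.isin(b, np.frombuffer(b"AG", dtype="S1"))
    diff = a != b
    ti = diff & (purine == purine_b)
    cls = np.where(ti, 1, np.where(diff, 2, 0))
    gc = np.frombuffer(b"GC", dtype="S1")
    gc_count = np.isin(a, gc).astype(np.int8) + np.isin(b, gc).astype(np.int8)
    return cls, gc_count


def _t92_from_counts(P: float, Q: float, theta: float) -> float:
    h = 2.0 * theta * (1.0 - theta)
    if P == 0.0 and Q == 0.0:
        return 0.0
    if h == 0.0:
        if P > 0.0:
            raise SaturationError(
                "transition differences observed but GC content is 0 or 1; "
                "T92 distance undefined"
            )
        arg1 = 1.0 - Q
    else:
        arg1 = 1.0 - P / h - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(
            f"divergence at saturation (P={P:.4f}, Q={Q:.4f}, theta={theta:.4f}); "
            "T92 distance undefined"
        )
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


def t92_distance(seq_a: str, seq_b: str) -> DistanceResult:
    """T92 distance between two equal-length sequences.

    Columns with gaps or ambiguity codes in either sequence are deleted
    pairwise.  theta is the GC fraction pooled over both sequences' compared
    columns.  Raises :class:`SaturationError` when the log arguments leave
    the estimator's domain.
    """
    a, b = _encode_pair(seq_a, seq_b)
    n = a.size
    if n == 0:
        raise ValueError("no pairwise-complete A/C/G/T columns to compare")
    cls, gc = _column_classes(a, b)
    P = float(np.count_nonzero(cls == 1)) / n
    Q = float(np.count_nonzero(cls == 2)) / n
    theta = float(gc.sum()) / (2 * n)
    d = _t92_from_counts(P, Q, theta)
    return DistanceResult(P=P, Q=Q, theta=theta, h=2 * theta * (1 - theta),
                          d=d, n_sites=n)


def bootstrap_se(
    seq_a: str,
    seq_b: str,
    replicates: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of the T92 distance.

    Sites are resampled with replacement ``replicates`` times (implemented
    as a multinomial draw over the distinct column types, which is
    equivalent and fast); the SE is the standard deviation of the replicate
    distances.  Saturated replicates are discarded; if every replicate
    saturates, an error is raised.
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    a, b = _encode_pair(seq_a, seq_b)
    n = a.size
    if n == 0:
        raise ValueError("no pairwise-complete A/C/G/T columns to compare")
    cls, gc = _column_classes(a, b)
    # joint column type: (difference class, GC count) -> 9 cells
    joint = cls.astype(np.int64) * 3 + gc
    counts = np.bincount(joint, minlength=9).astype(float)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, counts / n, size=replicates)
    cls_of = np.arange(9) // 3
    gc_of = np.arange(9) % 3
    P = draws[:, cls_of == 1].sum(axis=1) / n
    Q = draws[:, cls_of == 2].sum(axis=1) / n
    theta = (draws * gc_of).sum(axis=1) / (2.0 * n)
    h = 2.0 * theta * (1.0 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe_h = np.where(h > 0, h, 1.0)
        arg1 = np.where(h > 0, 1.0 - P / safe_h - Q, 1.0 - Q)
        arg2 = 1.0 - 2.0 * Q
        ok = (arg1 > 0) & (arg2 > 0) & ~((h == 0) & (P > 0))
        d = -h * np.log(np.where(ok, arg1, 1.0)) \
            - 0.5 * (1.0 - h) * np.log(np.where(ok, arg2, 1.0))
    d = d[ok]
    if d.size == 0:
        raise SaturationError("all bootstrap replicates saturated")
    if d.size == 1:
        return 0.0
    return float(np.std(d, ddof=1))


def t92_with_se(
    seq_a: str, seq_b: str, replicates: int = 1000, seed: int | None = None
) -> DistanceResult:
    res = t92_distance(seq_a, seq_b)
    se = bootstrap_se(seq_a, seq_b, replicates=replicates, seed=seed)
    return DistanceResult(P=res.P, Q=res.Q, theta=res.theta, h=res.h,
                          d=res.d, n_sites=res.n_sites, se=se)


def group_mean_distance(
    seqs_a: Sequence[str], seqs_b: Sequence[str]
) -> float:
    """Mean of all between-group pairwise T92 distances."""
    ds = [t92_distance(x, y).d for x in seqs_a for y in seqs_b]
    if not ds:
        raise ValueError("empty group")
    return float(np.mean(ds))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibratedAge:
    d_ingroup: float
    d_outgroup: float  # mean over outgroup comparisons
    t_outgroup: float
    t_point: float
    t_low: float
    t_high: float


def calibrate_divergence(
    d_ingroup: float,
    d_outgroups: Sequence[float],
    t_outgroup: float = 8.8e6,
    se_ingroup: float = 0.0,
) -> CalibratedAge:
    """Scale an ingroup distance to years via a dated outgroup split.

    t = t_outgroup * d_ingroup / mean(d_outgroups); the interval propagates
    the ingroup distance SE as (d +/- se) / mean(d_outgroups) * t_outgroup
    (the outgroup distance and calibration age are treated as fixed).
    """
    if not d_outgroups:
        raise ValueError("at least one outgroup distance is required")
    if any(d <= 0 for d in d_outgroups):
        raise ValueError("outgroup distances must be positive")
    if d_ingroup < 0 or se_ingroup < 0:
        raise ValueError("negative distance or SE")
    d_out = float(np.mean(d_outgroups))
    scale = t_outgroup / d_out
    t_point = d_ingroup * scale
    t_low = max(0.0, (d_ingroup - se_ingroup)) * scale
    t_high = (d_ingroup + se_ingroup) * scale
    return CalibratedAge(
        d_ingroup=d_ingroup, d_outgroup=d_out, t_outgroup=t_outgroup,
        t_point=t_point, t_low=t_low, t_high=t_high,
    )


# ---------------------------------------------------------------------------
# neighbor-joining topology (visualisation only)
# ---------------------------------------------------------------------------

def nj_tree_newick(ids: Sequence[str], seqs: Sequence[str]) -> str:
    """Neighbor-joining tree from the pairwise T92 distance matrix, as
    newick.  Intended for visual comparison only — no branch support or
    model selection is attempted."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = t92_distance(seqs[i], seqs[j]).d
    tree = nj(DistanceMatrix(mat, list(ids)))
    return str(tree).strip()
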