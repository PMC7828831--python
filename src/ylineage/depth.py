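"""Read-depth classification of candidate Y-chromosome sites.

Capture sequencing of the Y against a heterologous reference yields a
multi-modal pooled-depth distribution: a low mode of spurious/contaminant
alignments, a main mode of uniquely mapping (X-degenerate) sites, a mode at
roughly double depth where an X gametolog or second Y copy co-captures, and
a long tail of higher-copy repeats.  Sites are classified by which depth
window they fall in; apparent heterozygosity in a male is an independent
paralogy signal that disqualifies a site from the unique class regardless
of depth.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats


class SiteClass(str, enum.Enum):
    ERROR = "ERROR"
    UNIQUE_Y = "UNIQUE_Y"
    PARALOG_SUSPECT = "PARALOG_SUSPECT"  # unique-window depth but het-flagged
    TWO_PARALOG = "TWO_PARALOG"
    MULTI_PARALOG = "MULTI_PARALOG"


@dataclass(frozen=True)
class DepthProfile:
    """Pooled and per-sample read depth at one candidate site.

    ``pooled_depth`` is summed across all males of one species; ``het_flag``
    is set when any male received a heterozygous genotype call at the site
    (impossible on a single-copy Y locus, hence a paralogy flag).
    """

    site_index: int
    pooled_depth: int
    per_sample_depth: tuple[int, ...] = ()
    het_flag: bool = False

    def __post_init__(self) -> None:
        if self.pooled_depth < 0 or any(d < 0 for d in self.per_sample_depth):
            raise ValueError(f"site {self.site_index}: negative depth")
        if self.per_sample_depth and sum(self.per_sample_depth) != self.pooled_depth:
            raise ValueError(
                f"site {self.site_index}: pooled depth {self.pooled_depth} != "
                f"sum of per-sample depths {sum(self.per_sample_depth)}"
            )


@dataclass(frozen=True)
class DepthWindows:
    """Inclusive depth windows delimiting the four site classes.

    ERROR: depth <= error_max; UNIQUE_Y: unique_min..unique_max;
    TWO_PARALOG: unique_max+1..two_paralog_max; MULTI_PARALOG: above.
    """

    error_max: int
    unique_min: int
    unique_max: int
    two_paralog_max: int

    def __post_init__(self) -> None:
        if not (
            0 <= self.error_max
            < self.unique_min
            <= self.unique_max
            < self.two_paralog_max
        ):
            raise ValueError(
                "windows must satisfy 0 <= error_max < unique_min <= "
                f"unique_max < two_paralog_max, got {self}"
            )

    @classmethod
    def defaults(cls) -> "DepthWindows":
        """Windows used for the red fox panel: errors <10x, unique 10-160x,
        two paralogs 161-210x, more than two paralogs >210x."""
        return cls(error_max=9, unique_min=10, unique_max=160, two_paralog_max=210)

    def classify_depth(self, depth: int) -> SiteClass:
        if depth <= self.error_max:
            return SiteClass.ERROR
        if depth <= self.unique_max:
            return SiteClass.UNIQUE_Y
        if depth <= self.two_paralog_max:
            return SiteClass.TWO_PARALOG
        return SiteClass.MULTI_PARALOG


def suggest_windows(
    depths: Sequence[int],
    smoothing_bandwidth: float = 10.0,
    grid_points: int = 2048,
    min_prominence: float = 0.02,
) -> DepthWindows:
    """Propose depth windows from the modes of the pooled-depth distribution.

    A Gaussian kernel density (absolute bandwidth in depth units) is
    evaluated on a grid; window boundaries are placed at the deepest valley
    between consecutive detected modes.  With four or more modes the first
    three valleys delimit error / unique / two-paralog / multi-paralog; with
    exactly three modes they are read as unique / two-paralog / multi-paralog
    and the error class is left empty.  Deterministic for fixed input.

    Raises
    ------
    ValueError
        For degenerate input (fewer than 100 sites, zero variance) or a
        distribution with fewer than three modes, in which case windows must
        be set manually.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 100:
        raise ValueError(
            f"need >= 100 sites to estimate depth windows, got {depths.size}; "
            "set windows manually"
        )
    if smoothing_bandwidth <= 0:
        raise ValueError("smoothing_bandwidth must be positive")
    sd = depths.std()
    if sd == 0:
        raise ValueError(
            "all depths identical: no valleys to detect; set windows manually"
        )
    kde = stats.gaussian_kde(depths, bw_method=smoothing_bandwidth / sd)
    # extend below zero so a low-depth error mode is not a boundary artifact
    lo = -4 * smoothing_bandwidth
    hi = depths.max() + 4 * smoothing_bandwidth
    grid = np.linspace(lo, hi, grid_points)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens)
    if peaks.size:
        prominences = signal.peak_prominences(dens, peaks)[0]
        # prominence relative to each mode's own height, so minor modes are
        # not masked by the dominant unique-Y mode
        peaks = peaks[prominences >= min_prominence * dens[peaks]]
    if len(peaks) < 3:
        raise ValueError(
            f"detected only {len(peaks)} depth mode(s); the distribution is "
            "not multi-modal enough for automatic windows — set them manually"
        )
    peaks = peaks[:4]  # error?, unique, two-paralog, multi-paralog
    valleys = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = dens[a : b + 1]
        valleys.append(grid[a + int(np.argmin(seg))])
    if len(valleys) >= 3:
        error_max = max(0, int(math.floor(valleys[0])))
        unique_max = int(math.floor(valleys[1]))
        two_max = int(math.floor(valleys[2]))
    else:  # three modes: unique / two-paralog / multi-paralog
        error_max = 0
        unique_max = int(math.floor(valleys[0]))
        two_max = int(math.floor(valleys[1]))
    return DepthWindows(
        error_max=error_max,
        unique_min=error_max + 1,
        unique_max=unique_max,
        two_paralog_max=two_max,
    )


@dataclass
class ClassificationSummary:
    counts: dict[SiteClass, int]
    fractions: dict[SiteClass, float]
    n_sites: int
    n_unique_depth_window: int  # depth filter alone
    n_het_excluded: int  # additionally removed by the het flag

    def as_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "counts": {k.value: v for k, v in self.counts.items()},
            "fractions": {k.value: v for k, v in self.fractions.items()},
            "n_unique_depth_window": self.n_unique_depth_window,
            "n_het_excluded": self.n_het_excluded,
        }


def classify_sites(
    profiles: Sequence[DepthProfile], windows: DepthWindows
) -> tuple[list[SiteClass], ClassificationSummary]:
    """Label every site with exactly one depth class.

    Sites whose pooled depth falls in the unique window but that carry a
    heterozygous call in any male are labeled PARALOG_SUSPECT rather than
    UNIQUE_Y: both the depth window and the het filter must pass.  The
    summary reports each filter's marginal effect separately.
    """
    labels: list[SiteClass] = []
    n_unique_depth = 0
    n_het_excluded = 0
    for p in profiles:
        cls = windows.classify_depth(p.pooled_depth)
        if cls is SiteClass.UNIQUE_Y:
            n_unique_depth += 1
            if p.het_flag:
                cls = SiteClass.PARALOG_SUSPECT
                n_het_excluded += 1
        labels.append(cls)
    counts = {c: 0 for c in SiteClass}
    for lab in labels:
        counts[lab] += 1
    n = len(labels)
    fractions = {c: (counts[c] / n if n else 0.0) for c in SiteClass}
    summary = ClassificationSummary(
        counts=counts,
        fractions=fractions,
        n_sites=n,
        n_unique_depth_window=n_unique_depth,
        n_het_excluded=n_het_excluded,
    )
    return labels, summary


def depth_report(labels: Sequence[SiteClass]) -> dict:
    """Counts per class plus the unique-window percentage of all sites,
    rounded to one decimal for display."""
    if not labels:
        raise ValueError("no site labels to report on")
    counts = {c.value: 0 for c in SiteClass}
    for lab in labels:
        counts[lab.value] += 1
    total = len(labels)
    pct = round(100.0 * counts[SiteClass.UNIQUE_Y.value] / total, 1)
    return {
        "n_sites": total,
        "counts": counts,
        "unique_y_count": counts[SiteClass.UNIQUE_Y.value],
        "unique_y_pct": pct,
    }
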