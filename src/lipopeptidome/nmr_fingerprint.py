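"""HSQC fingerprint matching for lipopeptide dereplication.

A lipopeptide's CHα cross-peaks in a ¹H-¹³C HSQC spectrum form a compact
fingerprint: one peak per residue, at positions reproducible enough
(under identical acquisition conditions) that comparing a new isolate's
peak list against a reference library identifies the compound — and,
when the reference has resolved stereochemistry, settles that too,
without further chemical analysis.

Matching is an optimal one-to-one assignment between query and reference
peaks under a tolerance-normalized distance
``d = sqrt((Δh/tol_h)² + (Δc/tol_c)²)``; pairs with d > 1 are rejected.
The assignment is solved exactly (Hungarian algorithm on a
dummy-augmented cost matrix), so a crowded fingerprint region cannot be
mis-scored by greedy pairing.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

#: default matching tolerances (ppm): typical HSQC reproducibility
DEFAULT_TOL_H = 0.03
DEFAULT_TOL_C = 0.4
#: fraction of peaks that must pair up for a "match" verdict
COVERAGE_THRESHOLD = 0.9


class PeakInputError(ValueError):
    """Empty or malformed peak list."""


@dataclass(frozen=True)
class Peak:
    """One CHα cross-peak (¹H and ¹³C chemical shifts, ppm)."""

    id: str
    h_ppm: float
    c_ppm: float

    def __post_init__(self):
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.c_ppm)):
            raise ValueError(f"peak {self.id!r}: non-finite chemical shift")


@dataclass
class MatchResult:
    """Query-vs-reference peak assignment summary."""

    reference: str
    n_matched: int
    coverage: float  # matched / max(|query|, |ref|)
    shift_rmsd: float  # sqrt(mean(dh^2 + dc^2)) over matched pairs, ppm
    verdict: str  # match | no_match
    assignment: list[tuple[str, str]] = None  # (query peak id, ref peak id)

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.shift_rmsd < 0:
            raise ValueError("shift RMSD must be >= 0")


def match_peaks(
    query: Sequence[Peak],
    ref: Sequence[Peak],
    tol_h: float = DEFAULT_TOL_H,
    tol_c: float = DEFAULT_TOL_C,
    *,
    reference_name: str = "reference",
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> MatchResult:
    """Optimally assign query peaks to reference peaks within tolerance.

    The assignment minimizes the summed normalized distance; rejected
    pairs (d > 1) are handled by augmenting the cost matrix with dummy
    nodes at cost 1.  Verdict is ``match`` iff coverage reaches the
    threshold and the combined RMSD stays below the tolerance-scaled cap
    ``sqrt(tol_h² + tol_c²)``.
    """
    from scipy.optimize import linear_sum_assignment

    if not query or not ref:
        raise PeakInputError("query and reference peak lists must be non-empty")
    if tol_h <= 0 or tol_c <= 0:
        raise PeakInputError("tolerances must be positive")

    n, m = len(query), len(ref)
    d = np.zeros((n, m))
    for i, q in enumerate(query):
        for j, r in enumerate(ref):
            d[i, j] = math.hypot(
                (q.h_ppm - r.h_ppm) / tol_h, (q.c_ppm - r.c_ppm) / tol_c
            )
    # dummy augmentation: unmatched query/ref peaks cost 1 each
    size = n + m
    cost = np.ones((size, size))
    cost[:n, :m] = np.minimum(d, 2.0)
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)

    matched: list[tuple[int, int]] = [
        (i, j)
        for i, j in zip(rows, cols)
        if i < n and j < m and d[i, j] <= 1.0
    ]
    if matched:
        sq = [
            (query[i].h_ppm - ref[j].h_ppm) ** 2
            + (query[i].c_ppm - ref[j].c_ppm) ** 2
            for i, j in matched
        ]
        rmsd = math.sqrt(sum(sq) / len(sq))
    else:
        rmsd = 0.0
    coverage = len(matched) / max(n, m)
    rmsd_cap = math.hypot(tol_h, tol_c)
    verdict = (
        "match"
        if matched and coverage >= coverage_threshold and rmsd <= rmsd_cap
        else "no_match"
    )
    return MatchResult(
        reference=reference_name,
        n_matched=len(matched),
        coverage=coverage,
        shift_rmsd=rmsd,
        verdict=verdict,
        assignment=[(query[i].id, ref[j].id) for i, j in matched],
    )


def dereplicate(
    query: Sequence[Peak],
    library: dict[str, Sequence[Peak]],
    tol_h: float = DEFAULT_TOL_H,
    tol_c: float = DEFAULT_TOL_C,
    **kwargs,
) -> list[MatchResult]:
    """Rank library references against a query peak list.

    Results are sorted by (verdict, coverage desc, RMSD asc, name); the
    top entry is the dereplication call, the rest are runner-up scores.
    """
    if not library:
        raise PeakInputError("empty reference library")
    results = [
        match_peaks(query, peaks, tol_h, tol_c, reference_name=name, **kwargs)
        for name, peaks in library.items()
    ]
    results.sort(
        key=lambda r: (r.verdict != "match", -r.coverage, r.shift_rmsd, r.reference)
    )
    return results


# ---------------------------------------------------------------------------
# peak-list and library I/O (CSV: peak_id, h_ppm, c_ppm)


def read_peaks_csv(path: str | Path) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            peaks.append(
                Peak(row["peak_id"], float(row["h_ppm"]), float(row["c_ppm"]))
            )
    if not peaks:
        raise PeakInputError(f"no peaks in {path}")
    return peaks


def write_peaks_csv(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["peak_id", "h_ppm", "c_ppm"])
        for p in peaks:
            writer.writerow([p.id, f"{p.h_ppm:.4f}", f"{p.c_ppm:.3f}"])


def read_library(directory: str | Path) -> dict[str, list[Peak]]:
    """Load a reference library: a directory of CSVs with a manifest JSON.

    ``manifest.json`` maps compound name -> CSV filename.
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    return {
        name: read_peaks_csv(directory / filename)
        for name, filename in sorted(manifest.items())
    }


def write_library(
    library: dict[str, Sequence[Peak]], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, peaks in sorted(library.items()):
        filename = f"{name}.csv"
        write_peaks_csv(peaks, directory / filename)
        manifest[name] = filename
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def export_results_tsv(results: Sequence[MatchResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["reference", "n_matched", "coverage", "shift_rmsd", "verdict"]
        )
        for r in results:
            writer.writerow(
                [r.reference, r.n_matched, f"{r.coverage:.3f}",
                 f"{r.shift_rmsd:.4f}", r.verdict]
            )
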