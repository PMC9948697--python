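"""Module-level diversification events: duplication, deletion, exchange.

NRPS diversity within and between LP families is shaped by module
dynamics.  Three signatures are detectable from sequence alone:

* duplication — adjacent near-identical A domains within one system;
* deletion — a contiguous block of modules present in one system but
  absent from a relative, typically flanked by homologous modules that
  mediated recombinational excision;
* exchange — an aligned module pair whose substrate specificities differ
  while the neighbouring modules match, i.e. a swapped-in module.

Events are inferred from a global module-level alignment scored by
A-domain identity (C/E domains coadapt to their neighbours and are less
informative).  Windowed identity profiles over Blosum62-aligned
concatenated synthetases visualize the same events as sharp identity
drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ._align import blosum62_global, sequence_identity
from .nrps_parser import NrpsSystem

#: adjacent A-domain identity above which a duplication is called
DUPLICATION_THRESHOLD = 0.9
#: gap penalty (per module) in the module-level alignment
MODULE_GAP_PENALTY = 0.4
#: flanking-module identity required to support an exchange call
EXCHANGE_FLANK_IDENTITY = 0.8

_BINS = ((100.0, "full"), (30.0, "mid"), (0.0, "low"))


@dataclass
class IdentityProfile:
    """Sliding-window percent identity along a pairwise alignment."""

    positions: np.ndarray  # window centres (alignment columns)
    identity: np.ndarray  # percent per window
    window: int

    @property
    def bins(self) -> list[str]:
        """full (100), mid [30, 100), low (<30) — the three-colour scheme."""
        out = []
        for value in self.identity:
            if value >= 100.0:
                out.append("full")
            elif value >= 30.0:
                out.append("mid")
            else:
                out.append("low")
        return out


@dataclass
class EvolutionEvent:
    """One inferred diversification event."""

    kind: str  # duplication | deletion | exchange
    modules_a: tuple[int, ...]  # affected 1-based module indices, system A
    modules_b: tuple[int, ...]  # affected indices in system B (empty if n/a)
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("duplication", "deletion", "exchange"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class ModuleAlignment:
    """Module-level alignment of two systems plus inferred events."""

    pairs: list[tuple[Optional[int], Optional[int]]]  # 1-based or None (gap)
    scores: dict[tuple[int, int], float]
    events: list[EvolutionEvent]
    substitutions: list[tuple[int, int]]  # specificity mismatches at termini


ASequences = Union[NrpsSystem, Sequence[str]]


def _a_sequences(system: ASequences) -> list[str]:
    if isinstance(system, NrpsSystem):
        return [m.a_sequence or "" for m in system.modules]
    return list(system)


# ---------------------------------------------------------------------------
# windowed identity


def windowed_identity(
    a: str,
    b: str,
    window: int = 50,
    *,
    aligned: bool = False,
) -> IdentityProfile:
    """Percent identity in a sliding window over a global alignment.

    Sequences are Blosum62-aligned first unless ``aligned`` is set (then
    they must be equal-length gapped strings).  The window slides by one
    column; gap columns count as mismatches.
    """
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        col_a, col_b = a, b
    else:
        col_a, col_b = blosum62_global(a, b)
    ncols = len(col_a)
    if window > ncols:
        raise ValueError(f"window {window} exceeds alignment length {ncols}")
    match = np.array(
        [1.0 if (x == y and x != "-") else 0.0 for x, y in zip(col_a, col_b)]
    )
    kernel = np.ones(window)
    sums = np.convolve(match, kernel, mode="valid")
    identity = 100.0 * sums / window
    positions = np.arange(ncols - window + 1) + window // 2
    return IdentityProfile(positions=positions, identity=identity, window=window)


def plot_identity_profile(profile: IdentityProfile, path) -> None:
    """Three-bin coloured profile plot (full=green, mid=olive, low=red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"full": "#2ca02c", "mid": "#8c8c2c", "low": "#d62728"}
    fig, ax = plt.subplots(figsize=(8, 2.2))
    bins = profile.bins
    ax.scatter(
        profile.positions,
        profile.identity,
        c=[colors[b] for b in bins],
        s=4,
        linewidths=0,
    )
    ax.set_xlabel("alignment position")
    ax.set_ylabel(f"% identity (window={profile.window})")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# module-level alignment and events


def _needleman_wunsch_modules(
    seq_a: list[str],
    seq_b: list[str],
    identity_fn: Callable[[str, str], float],
    gap_penalty: float,
):
    n, m = len(seq_a), len(seq_b)
    scores = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            scores[i, j] = identity_fn(seq_a[i], seq_b[j])
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = -gap_penalty * np.arange(n + 1)
    dp[0, :] = -gap_penalty * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(
                dp[i - 1, j - 1] + scores[i - 1, j - 1],
                dp[i - 1, j] - gap_penalty,
                dp[i, j - 1] - gap_penalty,
            )
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and np.isclose(dp[i, j], dp[i - 1, j - 1] + scores[i - 1, j - 1])
        ):
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(dp[i, j], dp[i - 1, j] - gap_penalty):
            pairs.append((i, None))
            i -= 1
        else:
            pairs.append((None, j))
            j -= 1
    pairs.reverse()
    return pairs, scores


def align_modules(
    sys_a: ASequences,
    sys_b: ASequences,
    *,
    identity_fn: Callable[[str, str], float] = sequence_identity,
    gap_penalty: float = MODULE_GAP_PENALTY,
    specificities_a: Optional[Sequence[str]] = None,
    specificities_b: Optional[Sequence[str]] = None,
    duplication_threshold: float = DUPLICATION_THRESHOLD,
    flank_identity: float = EXCHANGE_FLANK_IDENTITY,
) -> ModuleAlignment:
    """Globally align two systems module-by-module and infer events.

    Match score is A-domain identity; unaligned runs become deletion
    events (reported as missing from the shorter system, with
    flanking-module homology as evidence); aligned pairs with differing
    specificities and matching flanks become exchanges (terminal pairs are
    reported as substitutions instead); adjacent near-identical modules
    within either system become duplications.
    """
    seq_a, seq_b = _a_sequences(sys_a), _a_sequences(sys_b)
    if not seq_a or not seq_b:
        raise ValueError("both systems need at least one module")
    pairs, scores = _needleman_wunsch_modules(seq_a, seq_b, identity_fn, gap_penalty)

    events: list[EvolutionEvent] = []
    substitutions: list[tuple[int, int]] = []
    score_map = {
        (ia, ib): float(scores[ia - 1, ib - 1])
        for ia, ib in pairs
        if ia is not None and ib is not None
    }

    # deletions: maximal runs of gaps
    run: list[tuple[Optional[int], Optional[int]]] = []

    def _flush_run(next_pair=None):
        nonlocal run
        if not run:
            return
        gap_in_b = run[0][1] is None
        missing = tuple(p[0] for p in run) if gap_in_b else tuple(p[1] for p in run)
        evidence = {}
        prev_aligned = None
        for p in pairs[: pairs.index(run[0])][::-1]:
            if p[0] is not None and p[1] is not None:
                prev_aligned = p
                break
        if prev_aligned:
            evidence["left_flank_identity"] = score_map[prev_aligned]
        if next_pair and next_pair[0] is not None and next_pair[1] is not None:
            evidence["right_flank_identity"] = score_map[next_pair]
        evidence["missing_from"] = "B" if gap_in_b else "A"
        events.append(
            EvolutionEvent(
                kind="deletion",
                modules_a=missing if gap_in_b else (),
                modules_b=() if gap_in_b else missing,
                evidence=evidence,
            )
        )
        run = []

    for idx, pair in enumerate(pairs):
        if pair[0] is None or pair[1] is None:
            if run and (run[0][0] is None) != (pair[0] is None):
                _flush_run(pair)
            run.append(pair)
        else:
            _flush_run(pair)
    _flush_run()

    # exchanges: specificity mismatch with matched flanks
    if specificities_a is not None and specificities_b is not None:
        aligned_pairs = [p for p in pairs if p[0] is not None and p[1] is not None]
        for k, (ia, ib) in enumerate(aligned_pairs):
            if specificities_a[ia - 1] == specificities_b[ib - 1]:
                continue
            terminal = k == 0 or k == len(aligned_pairs) - 1
            if terminal:
                substitutions.append((ia, ib))
                continue
            left, right = aligned_pairs[k - 1], aligned_pairs[k + 1]
            if (
                score_map[left] >= flank_identity
                and score_map[right] >= flank_identity
            ):
                events.append(
                    EvolutionEvent(
                        kind="exchange",
                        modules_a=(ia,),
                        modules_b=(ib,),
                        evidence={
                            "left_flank_identity": score_map[left],
                            "right_flank_identity": score_map[right],
                            "pair_identity": score_map[(ia, ib)],
                        },
                    )
                )
            else:
                substitutions.append((ia, ib))

    # duplications within each input system
    for which, seq in (("A", seq_a), ("B", seq_b)):
        for event in detect_duplications(seq, threshold=duplication_threshold):
            event.evidence["system"] = which
            if which == "B":
                event.modules_a, event.modules_b = (), event.modules_a
            events.append(event)

    return ModuleAlignment(
        pairs=pairs, scores=score_map, events=events, substitutions=substitutions
    )


def detect_duplications(
    system: ASequences,
    threshold: float = DUPLICATION_THRESHOLD,
) -> list[EvolutionEvent]:
    """Adjacent module pairs with A-domain identity >= threshold."""
    seqs = _a_sequences(system)
    if len(seqs) < 2:
        return []
    events = []
    for i in range(len(seqs) - 1):
        ident = sequence_identity(seqs[i], seqs[i + 1])
        if ident >= threshold:
            events.append(
                EvolutionEvent(
                    kind="duplication",
                    modules_a=(i + 1, i + 2),
                    modules_b=(),
                    evidence={"identity": float(ident)},
                )
            )
    return events


def export_events_tsv(events: Sequence[EvolutionEvent], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["kind", "modules_a", "modules_b", "evidence"])
        for ev in events:
            writer.writerow(
                [
                    ev.kind,
                    ",".join(map(str, ev.modules_a)),
                    ",".join(map(str, ev.modules_b)),
                    ";".join(f"{k}={v}" for k, v in sorted(ev.evidence.items())),
                ]
            )
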