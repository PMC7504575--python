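"""Degradome (PARE) analysis: miRNA target-site scoring, tag mapping,
cleavage-site categorization and differential degradation.

Target duplexes follow the standard plant-rule convention: the miRNA pairs
antiparallel with the transcript site; penalties are mismatch 1.0, G:U wobble
0.5, gap 2.0, all doubled across the functionally critical miRNA positions
2-13; a site is accepted when the total penalty is at most 4.5 (configurable).
The guided cleavage position is the transcript base paired to miRNA position
10 (the 5' nucleotide of the downstream cleavage fragment).

Degradome tags mark uncapped 5' ends of cleaved mRNAs; per-transcript position
profiles are normalized to transcripts per billion (TPB = raw x 1e9 / total
mapped tags in the library), and each candidate site is assigned a confidence
category 0-4 from its tag abundance relative to the transcript's maximum and
median (0 best, 4 worst).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_COMP = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G", "N": "N"}

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
CORE = (2, 13)  # inclusive miRNA positions with doubled penalties
DEFAULT_MAX_PENALTY = 4.5


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def _pair_cost(m: str, s: str) -> float:
    """Penalty for pairing miRNA base m against transcript (sense) base s."""
    m, s = m.upper().replace("U", "T"), s.upper().replace("U", "T")
    if m == "N" or s == "N":
        return MISMATCH
    if _COMP[m] == s:
        return 0.0
    if (m, s) in (("G", "T"), ("T", "G")):
        return WOBBLE
    return MISMATCH


def _weight(pos: int) -> float:
    return 2.0 if CORE[0] <= pos <= CORE[1] else 1.0


@dataclass
class TargetAlignment:
    """A scored miRNA/transcript duplex.

    Coordinates are 1-based inclusive on the transcript sense strand.
    ``states`` holds one of match/GU/mismatch/gap per miRNA position (5'->3').
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    penalty: float
    states: list[str]
    cleavage_pos: int
    accepted: bool = True

    def __post_init__(self) -> None:
        if not (self.start <= self.cleavage_pos <= self.end):
            raise ValueError("cleavage position outside the target site")


def score_duplex(
    mirna: str,
    site: str,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    site_start: int = 1,
    max_gaps: int = 1,
    max_penalty: float = DEFAULT_MAX_PENALTY,
) -> TargetAlignment:
    """Align one miRNA against one candidate site (antiparallel) by banded DP.

    The site is given 5'->3' on the transcript sense strand; its 3'-most base
    pairs the miRNA 5' end.  At most ``max_gaps`` gap (in either strand) is
    allowed, so ``len(site)`` must lie within ``len(mirna) +/- max_gaps``.
    Gap penalties are weighted by the miRNA position at which the gap occurs
    (a deleted miRNA base k uses position k; a site base inserted after k
    consumed miRNA bases uses position min(k+1, L)).  Ambiguous bases count
    as mismatches.
    """
    L, M = len(mirna), len(site)
    if abs(L - M) > max_gaps:
        raise ValueError(f"site length {M} outside miRNA length {L} +/- {max_gaps}")
    t = site[::-1]  # t[j] sits opposite mirna position j+1 in a gapless duplex

    INF = float("inf")
    # dp[g][i][j]: min penalty aligning mirna[:i] with t[:j] using g gaps
    dp = [[[INF] * (M + 1) for _ in range(L + 1)] for _ in range(max_gaps + 1)]
    back: dict[tuple[int, int, int], tuple[int, int, int, str]] = {}
    dp[0][0][0] = 0.0
    for g in range(max_gaps + 1):
        for i in range(L + 1):
            for j in range(M + 1):
                cur = dp[g][i][j]
                if cur == INF:
                    continue
                if i < L and j < M:  # pair mirna[i] with t[j]
                    c = cur + _pair_cost(mirna[i], t[j]) * _weight(i + 1)
                    if c < dp[g][i + 1][j + 1]:
                        dp[g][i + 1][j + 1] = c
                        back[(g, i + 1, j + 1)] = (g, i, j, "pair")
                if g < max_gaps and i < L:  # miRNA base unpaired (gap in site)
                    c = cur + GAP * _weight(i + 1)
                    if c < dp[g + 1][i + 1][j]:
                        dp[g + 1][i + 1][j] = c
                        back[(g + 1, i + 1, j)] = (g, i, j, "del")
                if g < max_gaps and j < M:  # extra site base (gap in miRNA)
                    c = cur + GAP * _weight(min(i + 1, L))
                    if c < dp[g + 1][i][j + 1]:
                        dp[g + 1][i][j + 1] = c
                        back[(g + 1, i, j + 1)] = (g, i, j, "ins")
    gbest = min(range(max_gaps + 1), key=lambda g: dp[g][L][M])
    penalty = dp[gbest][L][M]

    # traceback: per-miRNA-position states and the site base paired to pos 10
    states: list[str] = []
    paired_j: dict[int, int] = {}  # mirna position -> t index (0-based)
    node = (gbest, L, M)
    while node in back:
        g, i, j, op = back[node]
        if op == "pair":
            cost = _pair_cost(mirna[i], t[j])
            states.append("match" if cost == 0 else ("GU" if cost == WOBBLE else "mismatch"))
            paired_j[i + 1] = j
        elif op == "del":
            states.append("gap")
        node = (g, i, j)
    states.reverse()

    end = site_start + M - 1
    if 10 in paired_j:
        cleave = end - paired_j[10]  # t index j <-> sense coordinate end - j
    else:  # position 10 deleted: use its neighbour's partner
        near = min(paired_j, key=lambda p: abs(p - 10))
        cleave = end - paired_j[near]
    cleave = min(max(cleave, site_start), end)
    return TargetAlignment(
        mirna_id=mirna_id, transcript_id=transcript_id, start=site_start, end=end,
        penalty=penalty, states=states, cleavage_pos=cleave,
        accepted=penalty <= max_penalty,
    )


def find_target_sites(
    mirna: str,
    transcript: str,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
    max_penalty: float = DEFAULT_MAX_PENALTY,
    mode: str = "seed",
    seed_span: tuple[int, int] = (2, 9),
    max_gaps: int = 1,
) -> list[TargetAlignment]:
    """Scan a transcript for acceptable target sites of one miRNA.

    ``mode='seed'`` anchors candidate windows at exact reverse-complement
    matches of the miRNA seed (positions ``seed_span``, default 2-9) and runs
    the banded DP only there -- fast and adequate for near-complementary plant
    sites, whose core region tolerates very few edits under the doubled-core
    scoring.  ``mode='full'`` scores every window (exhaustive, for small
    inputs).  Overlapping hits are reduced to the best-penalty alignment per
    cleavage position.
    """
    mirna = mirna.upper().replace("U", "T")
    tx = transcript.upper().replace("U", "T")
    L, N = len(mirna), len(tx)
    hits: list[TargetAlignment] = []

    def try_window(start0: int, length: int) -> None:
        if start0 < 0 or start0 + length > N:
            return
        site = tx[start0:start0 + length]
        try:
            aln = score_duplex(
                mirna, site, mirna_id, transcript_id, site_start=start0 + 1,
                max_gaps=max_gaps, max_penalty=max_penalty,
            )
        except ValueError:
            return
        if aln.accepted:
            hits.append(aln)

    if mode == "seed":
        a, b = seed_span
        anchor = revcomp(mirna[a - 1:b])  # sense-strand match for seed pairing
        k = len(anchor)
        pos = tx.find(anchor)
        while pos != -1:
            # gapless: seed base b pairs sense coord pos+1 (0-based pos), site end
            # pairs miRNA position 1 at sense coord pos + k + (a-1) - 1
            end0 = pos + k + (a - 1) - 1  # 0-based inclusive end of the site
            for dlen in (0, -1, 1)[: max_gaps * 2 + 1]:
                length = L + dlen
                try_window(end0 - length + 1, length)
            pos = tx.find(anchor, pos + 1)
    elif mode == "full":
        for length in {L, L - max_gaps, L + max_gaps}:
            for s0 in range(0, N - length + 1):
                try_window(s0, length)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    best: dict[int, TargetAlignment] = {}
    for aln in hits:
        prev = best.get(aln.cleavage_pos)
        if prev is None or aln.penalty < prev.penalty:
            best[aln.cleavage_pos] = aln
    return [best[p] for p in sorted(best)]


def find_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_penalty: float = DEFAULT_MAX_PENALTY,
    mode: str = "seed",
) -> list[TargetAlignment]:
    """All accepted miRNA/transcript alignments over two catalogs."""
    out: list[TargetAlignment] = []
    for mid in sorted(mirnas):
        for tid in sorted(transcripts):
            out.extend(
                find_target_sites(
                    mirnas[mid], transcripts[tid], mid, tid,
                    max_penalty=max_penalty, mode=mode,
                )
            )
    return out


@dataclass
class PositionProfile:
    """Per-transcript degradome 5'-end profile for one library (1-based)."""

    transcript_id: str
    counts: dict[int, int]
    total_mapped: int  # all mapped tags in the library

    def tpb(self, position: int) -> float:
        if self.total_mapped == 0:
            return 0.0
        return self.counts.get(position, 0) * 1e9 / self.total_mapped


def build_tag_index(
    transcripts: Mapping[str, str], index_k: int = 20
) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> [(transcript id, 0-based start)] lookup for exact tag mapping."""
    index: dict[str, list[tuple[str, int]]] = {}
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        for i in range(0, len(seq) - index_k + 1):
            index.setdefault(seq[i:i + index_k], []).append((tid, i))
    return index


def map_tags(
    tags: Sequence[str],
    transcripts: Mapping[str, str],
    index_k: int = 20,
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> dict[str, PositionProfile]:
    """Map tags to transcripts by exact full-length match.

    The recorded position is the transcript coordinate of the tag's 5' end.
    A tag hitting several transcripts is counted once in each; several
    occurrences within one transcript count only at the 5'-most.  Returns
    one profile per transcript that received at least one tag, all sharing
    the library's total mapped-tag count.  A prebuilt ``index`` (from
    :func:`build_tag_index`) can be shared across libraries.
    """
    if index is None:
        index = build_tag_index(transcripts, index_k)

    per_tx: dict[str, dict[int, int]] = {}
    mapped = 0
    for tag in tags:
        tag = tag.upper()
        if len(tag) < index_k:
            continue
        seen: set[str] = set()
        hit = False
        for tid, i in index.get(tag[:index_k], ()):
            if tid in seen:
                continue  # 5'-most occurrence only
            if transcripts[tid].upper().startswith(tag, i):
                seen.add(tid)
                per_tx.setdefault(tid, {})[i + 1] = per_tx.setdefault(tid, {}).get(i + 1, 0) + 1
                hit = True
        if hit:
            mapped += 1
    return {
        tid: PositionProfile(tid, counts, mapped) for tid, counts in per_tx.items()
    }


def categorize(position: int, profile: PositionProfile) -> int | None:
    """Cleavage-confidence category 0-4 from the transcript's tag profile.

    Let r be the raw count at the queried position, M the transcript maximum
    and med the median over positions carrying >= 1 read.  Precedence (ties
    resolved in favour of the max-based rules): r = 0 -> no event (None);
    r = 1 -> 4; r = M attained uniquely -> 0; r = M attained at several
    positions -> 1; med < r < M -> 2; otherwise (1 < r <= med) -> 3.
    """
    r = profile.counts.get(position, 0)
    if r == 0:
        return None
    if r == 1:
        return 4
    occupied = [c for c in profile.counts.values() if c > 0]
    M = max(occupied)
    if r == M:
        return 0 if occupied.count(M) == 1 else 1
    med = _median(occupied)
    if r > med:
        return 2
    return 3


def _median(values: list[int]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


@dataclass
class CleavageEvent:
    """A degradome-supported cleavage site for one alignment in one library."""

    alignment: TargetAlignment
    library_id: str
    position: int  # observed tag position chosen within the shift window
    raw: int
    tpb: float
    category: int

    def __post_init__(self) -> None:
        if self.category not in (0, 1, 2, 3, 4):
            raise ValueError("category must be 0-4")


def call_targets(
    alignments: Iterable[TargetAlignment],
    profiles: Mapping[str, Mapping[str, PositionProfile]],
    shift_window: int = 1,
    category_max: int = 4,
) -> list[CleavageEvent]:
    """Turn alignments into cleavage events wherever tags support them.

    ``profiles`` maps library id -> transcript id -> profile.  An alignment
    yields an event in a library when a position within +/- ``shift_window``
    of the predicted cleavage coordinate carries >= 1 tag; among candidates
    the highest count wins, then the closest to the prediction, then the
    smallest coordinate.  Events with category > ``category_max`` are dropped.
    """
    events: list[CleavageEvent] = []
    for aln in alignments:
        for lib in sorted(profiles):
            prof = profiles[lib].get(aln.transcript_id)
            if prof is None:
                continue
            cands = [
                (p, prof.counts.get(p, 0))
                for p in range(aln.cleavage_pos - shift_window, aln.cleavage_pos + shift_window + 1)
                if prof.counts.get(p, 0) >= 1
            ]
            if not cands:
                continue
            pos, raw = min(cands, key=lambda pc: (-pc[1], abs(pc[0] - aln.cleavage_pos), pc[0]))
            cat = categorize(pos, prof)
            if cat is None or cat > category_max:
                continue
            events.append(
                CleavageEvent(aln, lib, pos, raw, prof.tpb(pos), cat)
            )
    return events


def events_table(events: Iterable[CleavageEvent]) -> pd.DataFrame:
    rows = [
        {
            "mirna": e.alignment.mirna_id,
            "transcript": e.alignment.transcript_id,
            "site_start": e.alignment.start,
            "site_end": e.alignment.end,
            "cleavage_pos": e.position,
            "raw": e.raw,
            "tpb": e.tpb,
            "category": e.category,
            "penalty": e.alignment.penalty,
            "library": e.library_id,
        }
        for e in events
    ]
    cols = ["mirna", "transcript", "site_start", "site_end", "cleavage_pos",
            "raw", "tpb", "category", "penalty", "library"]
    return pd.DataFrame(rows, columns=cols)


def tplot_table(
    profile: PositionProfile, flagged_positions: Iterable[int] = ()
) -> pd.DataFrame:
    """Plot-ready per-position TPB table with the predicted site(s) flagged."""
    flags = set(flagged_positions)
    rows = [
        {
            "transcript": profile.transcript_id,
            "position": p,
            "raw": c,
            "tpb": profile.tpb(p),
            "flag": int(p in flags),
        }
        for p, c in sorted(profile.counts.items())
    ]
    return pd.DataFrame(rows, columns=["transcript", "position", "raw", "tpb", "flag"])


def differential_degradation(
    stress_events: Iterable[CleavageEvent],
    control_events: Iterable[CleavageEvent],
    floor: float = 0.001,
) -> pd.DataFrame:
    """log2 TPB ratio (stress/control) per (miRNA, transcript) target.

    Up-regulation means a higher degree of miRNA-induced degradation under
    stress; down-regulation means lower degradation.  Targets absent in one
    condition contribute TPB 0 and are floored before the ratio.
    """
    def best(events):
        out: dict[tuple[str, str], float] = {}
        for e in events:
            key = (e.alignment.mirna_id, e.alignment.transcript_id)
            out[key] = max(out.get(key, 0.0), e.tpb)
        return out

    s, c = best(stress_events), best(control_events)
    rows = []
    for key in sorted(set(s) | set(c)):
        ts, tc = s.get(key, 0.0), c.get(key, 0.0)
        lfc = math.log2(max(ts, floor) / max(tc, floor))
        rows.append(
            {
                "mirna": key[0], "transcript": key[1],
                "tpb_stress": ts, "tpb_control": tc, "log2fc": lfc,
                "direction": "up" if lfc > 0 else ("down" if lfc < 0 else "ns"),
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna", "transcript", "tpb_stress", "tpb_control", "log2fc", "direction"]
    )
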