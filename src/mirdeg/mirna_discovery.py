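"""Small-RNA processing and miRNA catalog construction.

Adapter-trimmed reads are length-filtered (18-26 nt) and collapsed to unique
sequences.  Known-miRNA matching tolerates end-shifts of up to 2 nt at either
terminus plus at most one internal substitution, and encodes the observed
variant in the record id the way mature-variant catalogs print them:

* ``_L+n`` / ``_L-n`` — 3' end longer / shorter by n nt
* ``_R+n`` / ``_R-n`` — 5' end longer / shorter by n nt
* ``_kssPXY`` — k substitutions; each as position P (1-based on the read),
  catalog base X, read base Y (e.g. ``_1ss9CG``)
* ``-p5`` / ``-p3`` — a non-canonical mature taken directly from a known
  precursor arm

Reads matching no catalog entry but mapping exactly to the reference and
folding into a hairpin (see :mod:`mirdeg.folding`) become novel (G5) miRNAs.
Known records are tiered G1-G4 ("conserved"): G1 mature+precursor both known
and the precursor maps to the reference; G2 mature known but its precursor
entry comes from another species; G3 mature known with no precursor mapping;
G4 variant-matched mature whose precursor is recovered from the reference.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .folding import HairpinCandidate, evaluate_hairpin, max_pairing

logger = logging.getLogger(__name__)

MIN_LEN, MAX_LEN = 18, 26


@dataclass
class SmallRNALibrary:
    """Collapsed unique-read table for one sample."""

    sample: str
    unique_reads: Counter
    total_clean: int

    def length_histogram(self) -> pd.Series:
        h = Counter()
        for seq, n in self.unique_reads.items():
            h[len(seq)] += n
        return pd.Series(dict(sorted(h.items())), dtype=int)


@dataclass
class MiRNARecord:
    """One mature miRNA with provenance and per-sample counts."""

    id: str
    sequence: str
    source: str  # 'known' | 'novel'
    group: str = ""
    precursor_id: str | None = None
    arm: str | None = None
    variant: bool = False
    precursor_in_catalog: bool = False
    precursor_maps: bool = False
    species_match: bool = True
    coordinates: tuple[str, int, int] | None = None  # (ref id, start, end) 1-based
    counts: dict[str, int] = field(default_factory=dict)
    hairpin: HairpinCandidate | None = None


def preprocess_reads(
    reads: Iterable[str],
    sample: str = "sample",
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> SmallRNALibrary:
    """Length-filter and collapse adapter-trimmed reads into a library."""
    uniq: Counter = Counter()
    total = 0
    for r in reads:
        r = r.strip().upper()
        if min_len <= len(r) <= max_len:
            uniq[r] += 1
            total += 1
    if total == 0:
        logger.warning("sample %s: no reads passed the %d-%d nt filter", sample, min_len, max_len)
    return SmallRNALibrary(sample=sample, unique_reads=uniq, total_clean=total)


def _enumerate_variants(
    mature_id: str, mature: str, precursor: str | None, max_shift: int = 2
) -> Iterable[tuple[str, str, float]]:
    """Yield (variant sequence, id suffix, badness score) for one catalog entry.

    Shifts are trims of the mature or extensions into its precursor context;
    substitution variants are generated on top of each shifted template.
    Score = total shifted nt + 2.5 per substitution, so exact < shifted <
    substituted at equal shift.
    """
    ctx5 = ctx3 = ""
    if precursor and mature in precursor:
        i = precursor.index(mature)
        ctx5 = precursor[max(0, i - max_shift):i]
        ctx3 = precursor[i + len(mature):i + len(mature) + max_shift]

    def shifted(d5: int, d3: int) -> str | None:
        seq = mature
        if d5 < 0:
            seq = seq[-d5:]
        elif d5 > 0:
            if len(ctx5) < d5:
                return None
            seq = ctx5[len(ctx5) - d5:] + seq
        if d3 < 0:
            seq = seq[:len(seq) + d3] if len(seq) + d3 > 0 else None
        elif d3 > 0:
            if len(ctx3) < d3:
                return None
            seq = seq + ctx3[:d3]
        return seq

    for d5 in range(-max_shift, max_shift + 1):
        for d3 in range(-max_shift, max_shift + 1):
            base = shifted(d5, d3)
            if base is None or len(base) < MIN_LEN or len(base) > MAX_LEN:
                continue
            suffix = ""
            if d3:
                suffix += f"_L{d3:+d}"
            if d5:
                suffix += f"R{d5:+d}" if d3 else f"_R{d5:+d}"
            shift_score = abs(d5) + abs(d3)
            yield base, suffix, float(shift_score)
            for pos in range(len(base)):
                ref_base = base[pos]
                for alt in "ACGT":
                    if alt == ref_base:
                        continue
                    var = base[:pos] + alt + base[pos + 1:]
                    sub_suffix = f"{suffix}_1ss{pos + 1}{ref_base}{alt}"
                    yield var, sub_suffix, shift_score + 2.5


def build_variant_index(
    catalog_matures: Mapping[str, str],
    catalog_precursors: Mapping[str, str] | None = None,
    max_shift: int = 2,
) -> dict[str, tuple[str, str, float]]:
    """Map every tolerated variant sequence to its best (id, suffix, score).

    Ties on score resolve to the lexicographically lowest catalog id, making
    read assignment deterministic and unambiguous.
    """
    precursors = catalog_precursors or {}
    index: dict[str, tuple[str, str, float]] = {}
    for mid in sorted(catalog_matures):
        mat = catalog_matures[mid]
        for seq, suffix, score in _enumerate_variants(mid, mat, precursors.get(mid), max_shift):
            prev = index.get(seq)
            if prev is None or score < prev[2]:
                index[seq] = (mid, suffix, score)
    return index


def match_known_mirnas(
    lib: SmallRNALibrary,
    catalog_matures: Mapping[str, str],
    catalog_precursors: Mapping[str, str] | None = None,
    variant_index: dict[str, tuple[str, str, float]] | None = None,
) -> list[MiRNARecord]:
    """Assign library reads to catalog miRNAs, summing counts per record.

    A read matches if identical to a mature, length-shifted by <= 2 nt at
    either end, or carrying exactly one internal substitution (combinations
    allowed); unmatched reads that sit verbatim inside a known precursor
    become arm-derived ``-p5``/``-p3`` records.
    """
    if not catalog_matures:
        raise ValueError("catalog is empty")
    if variant_index is None:
        variant_index = build_variant_index(catalog_matures, catalog_precursors)
    precursors = catalog_precursors or {}

    records: dict[str, MiRNARecord] = {}
    for seq, n in sorted(lib.unique_reads.items()):
        hit = variant_index.get(seq)
        if hit is not None:
            mid, suffix, _ = hit
            rid = mid + suffix
            rec = records.get(rid)
            if rec is None:
                rec = MiRNARecord(
                    id=rid, sequence=seq, source="known", variant=bool(suffix),
                    precursor_id=mid if mid in precursors else None,
                    precursor_in_catalog=mid in precursors,
                )
                records[rid] = rec
            rec.counts[lib.sample] = rec.counts.get(lib.sample, 0) + n
            continue
        for pid in sorted(precursors):
            pre = precursors[pid]
            if seq in pre:
                i = pre.index(seq)
                arm = "5p" if i + len(seq) / 2 < len(pre) / 2 else "3p"
                rid = f"{pid}-p5" if arm == "5p" else f"{pid}-p3"
                rec = records.get(rid)
                if rec is None:
                    rec = MiRNARecord(
                        id=rid, sequence=seq, source="known", variant=True,
                        precursor_id=pid, arm=arm, precursor_in_catalog=True,
                    )
                    records[rid] = rec
                rec.counts[lib.sample] = rec.counts.get(lib.sample, 0) + n
                break
    return [records[k] for k in sorted(records)]


def map_read(read: str, reference: Mapping[str, str]) -> list[tuple[str, int]]:
    """Exact forward-strand loci of a read: (reference id, 1-based start)."""
    loci = []
    for rid in sorted(reference):
        seq = reference[rid]
        start = seq.find(read)
        while start != -1:
            loci.append((rid, start + 1))
            start = seq.find(read, start + 1)
    return loci


def discover_novel_mirnas(
    unmatched: Mapping[str, int],
    reference: Mapping[str, str],
    sample: str = "sample",
    flank: int = 120,
    max_loci: int = 20,
    min_paired: int = 16,
    max_unpaired_run: int = 4,
    min_loop: int = 3,
    max_candidates: int | None = None,
    fold_fn=max_pairing,
) -> list[MiRNARecord]:
    """Novel (G5) miRNA discovery from reads absent from the catalog.

    Each read must map exactly to the reference (reads hitting more than
    ``max_loci`` loci are discarded as repeat-derived).  A window of the read
    +/- ``flank`` nt is folded by base-pair maximization with both arm
    placements tried (the read-side flank trimmed to 20 nt on one side at a
    time); the read is accepted as a novel mature when the hairpin criteria
    hold (see :func:`mirdeg.folding.evaluate_hairpin`).
    """
    out: list[MiRNARecord] = []
    items = sorted(unmatched.items(), key=lambda kv: (-kv[1], kv[0]))
    if max_candidates is not None:
        items = items[:max_candidates]
    n_novel = 0
    for seq, count in items:
        loci = map_read(seq, reference)
        if not loci:
            continue
        if len(loci) > max_loci:
            logger.info("read %s... maps to %d loci; discarded as repeat-derived",
                        seq[:12], len(loci))
            continue
        rid_ref, start = loci[0]
        refseq = reference[rid_ref]
        s0 = start - 1
        best: HairpinCandidate | None = None
        for up, down in ((20, flank), (flank, 20)):
            w0 = max(0, s0 - up)
            w1 = min(len(refseq), s0 + len(seq) + down)
            cand = evaluate_hairpin(
                refseq[w0:w1], s0 - w0, s0 - w0 + len(seq),
                min_loop=min_loop, min_paired=min_paired,
                max_unpaired_run=max_unpaired_run, fold_fn=fold_fn,
            )
            if cand.accepted and (best is None or cand.mature_star_pairs > best.mature_star_pairs):
                best = cand
        if best is None:
            continue
        n_novel += 1
        rec = MiRNARecord(
            id=f"novel-m{n_novel:04d}", sequence=seq, source="novel", group="G5",
            arm=best.arm, coordinates=(rid_ref, start, start + len(seq) - 1),
            counts={sample: count}, hairpin=best,
        )
        out.append(rec)
    return out


def assign_group(record: MiRNARecord) -> str:
    """Deterministic G1-G5 tier for a record (total over all records)."""
    if record.source == "novel":
        return "G5"
    if record.variant:
        return "G4" if record.precursor_maps or record.precursor_in_catalog else "G3"
    if record.precursor_in_catalog and record.precursor_maps:
        return "G1" if record.species_match else "G2"
    return "G3"


def assign_groups(records: Sequence[MiRNARecord]) -> None:
    for rec in records:
        rec.group = assign_group(rec)


def records_to_count_matrix(
    records: Sequence[MiRNARecord], samples: Sequence[str]
) -> CountMatrix:
    data = {
        rec.id: [rec.counts.get(s, 0) for s in samples] for rec in records
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(samples)).astype(np.int64)
    return CountMatrix(df.sort_index())


def catalog_table(records: Sequence[MiRNARecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "sequence": r.sequence,
            "source": r.source,
            "group": r.group,
            "reference": r.coordinates[0] if r.coordinates else "",
            "start": r.coordinates[1] if r.coordinates else 0,
            "end": r.coordinates[2] if r.coordinates else 0,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["id", "sequence", "source", "group", "reference", "start", "end"])


def presence_partition(
    cm: CountMatrix,
    factor: str = "treatment",
    presence_cpm: float = 1.0,
    min_replicates: int = 2,
) -> dict[frozenset, int]:
    """Venn region counts of miRNA presence across the levels of a factor.

    A miRNA is "expressed" in a level when its CPM is >= ``presence_cpm`` in
    at least ``min_replicates`` samples of that level (pooled over the other
    factors).  Returns exact region counts: key = frozenset of levels whose
    membership is exactly that region; counts over all regions sum to the
    union size.
    """
    from .expression_stats import normalize_cpm

    table = cm.sample_table()
    levels = list(dict.fromkeys(table[factor]))
    cpm = normalize_cpm(cm)
    membership: dict[str, frozenset] = {}
    present = {}
    for lv in levels:
        cols = table.index[table[factor] == lv]
        present[lv] = (cpm[cols] >= presence_cpm).sum(axis=1) >= min_replicates
    for feat in cm.features:
        s = frozenset(lv for lv in levels if present[lv][feat])
        if s:
            membership[feat] = s
    regions: dict[frozenset, int] = {}
    for r in range(1, len(levels) + 1):
        for combo in combinations(levels, r):
            regions[frozenset(combo)] = 0
    for s in membership.values():
        regions[s] += 1
    return regions
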