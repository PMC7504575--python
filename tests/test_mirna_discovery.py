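"""Read preprocessing, variant-aware matching, hairpin discovery, grouping
and presence partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from mirdeg.containers import CountMatrix, ExperimentDesign
from mirdeg.folding import evaluate_hairpin, max_pairing
from mirdeg.mirna_discovery import (
    MiRNARecord,
    SmallRNALibrary,
    assign_group,
    build_variant_index,
    discover_novel_mirnas,
    match_known_mirnas,
    preprocess_reads,
    presence_partition,
)
from mirdeg.degradome import revcomp


# ---------------------------------------------------------------- preprocess

def test_preprocess_collapses_and_counts():
    lib = preprocess_reads(["ACGT" * 5] * 3, sample="s")
    assert lib.unique_reads == {"ACGT" * 5: 3}
    assert lib.total_clean == 3


def test_preprocess_length_filter():
    lib = preprocess_reads(["A" * 17, "A" * 18, "A" * 26, "A" * 27])
    assert set(lib.unique_reads) == {"A" * 18, "A" * 26}


def test_preprocess_histogram_modes():
    reads = ["AC" * 10 + "A"] * 60 + ["GT" * 12] * 30 + ["ACGTA" * 4] * 10
    h = preprocess_reads(reads).length_histogram()
    top2 = set(h.sort_values(ascending=False).index[:2])
    assert top2 == {21, 24}


def test_preprocess_empty_is_warning_not_error(caplog):
    lib = preprocess_reads([])
    assert lib.total_clean == 0


# ------------------------------------------------------------------ matching

CATALOG = {
    "osa-miR001": "ACGTACGTACGTACGTACGTA",
    "tae-miR002": "TTGCATGCATGCATGCATGCA",
}
ARM3 = "CCATTCCGGAAGGTTCAACCT"  # a distinct 3'-arm mature, outside variant range
PRECURSORS = {
    "osa-miR001": "GG" + "ACGTACGTACGTACGTACGTA" + "CCAATT" + ARM3 + "AA",
}


def _match_one(read):
    lib = SmallRNALibrary("s", {read: 5}, 5)
    recs = match_known_mirnas(lib, CATALOG, PRECURSORS)
    assert len(recs) == 1
    return recs[0]


def test_exact_match_keeps_id():
    rec = _match_one(CATALOG["osa-miR001"])
    assert rec.id == "osa-miR001"
    assert not rec.variant
    assert rec.counts["s"] == 5


def test_single_substitution_suffix():
    mat = CATALOG["tae-miR002"]
    read = mat[:8] + ("A" if mat[8] != "A" else "C") + mat[9:]
    rec = _match_one(read)
    assert rec.id == f"tae-miR002_1ss9{mat[8]}{read[8]}"


def test_three_prime_trim_suffix():
    rec = _match_one(CATALOG["tae-miR002"][:-1])
    assert rec.id == "tae-miR002_L-1"


def test_five_prime_extension_from_precursor():
    read = "G" + CATALOG["osa-miR001"]  # precursor context is "GG"
    rec = _match_one(read)
    assert rec.id == "osa-miR001_R+1"


def test_combined_shift_and_substitution():
    base = CATALOG["tae-miR002"][:-1]
    alt = "C" if base[14] != "C" else "G"
    read = base[:14] + alt + base[15:]
    rec = _match_one(read)
    assert rec.id == f"tae-miR002_L-1_1ss15{base[14]}{alt}"


def test_tie_resolves_to_lowest_id():
    cat = {"b-mir": "ACGTACGTACGTACGTACGTA", "a-mir": "ACGTACGTACGTACGTACGTA"}
    lib = SmallRNALibrary("s", {"ACGTACGTACGTACGTACGTA": 1}, 1)
    recs = match_known_mirnas(lib, cat)
    assert [r.id for r in recs] == ["a-mir"]


def test_precursor_arm_derived_record():
    rec = _match_one(ARM3)  # 3'-arm sequence, not a catalog mature
    assert rec.id == "osa-miR001-p3"
    assert rec.arm == "3p"


def test_empty_catalog_errors():
    with pytest.raises(ValueError):
        match_known_mirnas(SmallRNALibrary("s", {}, 0), {})


def test_counts_sum_bounded_by_library_total(small_ref):
    from mirdeg.synthio import simulate_srna_reads

    reads = simulate_srna_reads(small_ref, 2000, seed=3)
    lib = preprocess_reads(reads)
    recs = match_known_mirnas(lib, small_ref.mirna_matures, small_ref.mirna_precursors)
    assert sum(r.counts.get("sample", 0) for r in recs) <= lib.total_clean


# ------------------------------------------------------------------- folding

def test_perfect_inverted_repeat_accepted():
    mature = "ACGTTGCAACGGTACCGGTTACAG"[:24]
    window = mature + "AATTAA" + revcomp(mature)
    cand = evaluate_hairpin(window, 0, len(mature))
    assert cand.accepted
    assert cand.arm == "5p"
    assert cand.mature_star_pairs >= 16
    assert cand.loop_length >= 3


def test_homopolymer_window_rejected():
    cand = evaluate_hairpin("A" * 60, 10, 31)
    assert not cand.accepted


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(12, 60))
def test_folding_dp_matches_bruteforce(seed, n):
    """DP pair-maximization equals independent top-down enumeration (<=60 nt)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGU"), size=n))
    count, pairs = max_pairing(seq)
    assert count == oracles.brute_max_pairs(seq)
    assert count == len(pairs)
    # structure is nested and respects the loop constraint
    for i, j in pairs:
        assert j - i > 3
    flat = [x for ij in pairs for x in ij]
    assert len(flat) == len(set(flat))


def test_discover_novel_on_planted_hairpin(small_ref):
    novel_id = sorted(small_ref.novel_hairpins)[0]
    tid, mat, start = small_ref.novel_hairpins[novel_id]
    recs = discover_novel_mirnas({mat: 10}, small_ref.transcripts)
    assert len(recs) == 1
    assert recs[0].group == "G5"
    assert recs[0].coordinates[0] == tid
    assert recs[0].hairpin.accepted


def test_discover_rejects_unmappable_read(small_ref):
    assert discover_novel_mirnas({"N" * 21: 5}, small_ref.transcripts) == []


def test_repeat_derived_read_discarded():
    mature = "ACGTACGTACGTACGTACGTA"
    ref = {f"t{i}": ("C" * 30 + mature + "G" * 30) for i in range(25)}
    assert discover_novel_mirnas({mature: 5}, ref, max_loci=20) == []


# ------------------------------------------------------------------ grouping

def _rec(**kw):
    base = dict(id="x", sequence="A" * 21, source="known")
    base.update(kw)
    return MiRNARecord(**base)


@pytest.mark.parametrize(
    "kw,expected",
    [
        (dict(source="novel"), "G5"),
        (dict(precursor_in_catalog=True, precursor_maps=True, species_match=True), "G1"),
        (dict(precursor_in_catalog=True, precursor_maps=True, species_match=False), "G2"),
        (dict(precursor_in_catalog=False, precursor_maps=False), "G3"),
        (dict(variant=True, precursor_maps=True), "G4"),
    ],
)
def test_group_decision_table(kw, expected):
    assert assign_group(_rec(**kw)) == expected


def test_grouping_total_over_records(small_ref):
    from mirdeg.synthio import simulate_srna_reads
    from mirdeg.mirna_discovery import assign_groups

    reads = simulate_srna_reads(small_ref, 1000, seed=1)
    lib = preprocess_reads(reads)
    recs = match_known_mirnas(lib, small_ref.mirna_matures, small_ref.mirna_precursors)
    assign_groups(recs)
    assert all(r.group in {"G1", "G2", "G3", "G4", "G5"} for r in recs)


# ---------------------------------------------------------- presence / Venn

def _presence_matrix(membership, design):
    """Counts where feature f has CPM>=1 in all replicates of its treatments."""
    import pandas as pd

    samples = design.sample_names()
    table = design.sample_table(samples)
    rows = {}
    for feat, treatments in membership.items():
        rows[feat] = [
            1000 if table.loc[s, "treatment"] in treatments else 0 for s in samples
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    libs = df.sum(axis=0).astype(float).replace(0, 1.0) * 0 + 1e6
    return CountMatrix(df, libs)


def test_presence_center_and_disjoint(one_genotype_design):
    cm = _presence_matrix(
        {"all4": {"CG", "WS", "HS", "WH"}, "only_cg": {"CG"}, "only_ws": {"WS"}},
        one_genotype_design,
    )
    regions = presence_partition(cm, "treatment")
    assert regions[frozenset({"CG", "WS", "HS", "WH"})] == 1
    assert regions[frozenset({"CG"})] == 1
    assert regions[frozenset({"WS"})] == 1
    assert regions[frozenset({"CG", "WS"})] == 0
    assert sum(regions.values()) == 3


def test_presence_regions_match_bruteforce(one_genotype_design):
    rng = np.random.default_rng(42)
    treatments = ["CG", "WS", "HS", "WH"]
    membership = {}
    for i in range(200):
        k = int(rng.integers(0, 5))
        membership[f"m{i:03d}"] = set(rng.choice(treatments, size=k, replace=False))
    cm = _presence_matrix(membership, one_genotype_design)
    regions = presence_partition(cm, "treatment")
    expected = oracles.brute_venn_regions(
        {f: s for f, s in membership.items() if s}, treatments
    )
    assert regions == expected
    assert sum(regions.values()) == sum(1 for s in membership.values() if s)
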