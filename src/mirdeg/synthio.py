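"""Seeded synthetic multi-omics generator emulating the factorial stress study.

The generator builds a transcript reference with miRNA catalog (matures exact
substrings of hairpin precursors), plants near-perfect-complementary target
sites, and simulates the three sequencing layers with the statistical
structure the analysis assumes:

* small-RNA counts — negative-binomial noise around lognormal baselines with
  planted log2 effects in stressed samples, plus a read-length distribution
  with the classic two modes at 21 and 24 nt;
* gene-level counts — same model; genes in planted antagonistic modules
  (coupling -1) receive the opposite-signed effect of their miRNA partner;
* degradome tags — exact 20-21 nt transcript substrings, concentrated at the
  planted cleavage positions over a uniform background.

All randomness flows from one top-level seed through numpy's SeedSequence
spawning scheme, so every artifact is byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExperimentDesign, ReferenceBundle, SyntheticTruth
from .degradome import revcomp

_BASES = np.array(list("ACGT"))

# stable stream labels for the seed-splitting scheme (documented in methods)
_STREAMS = ("reference", "truth", "srna", "genes", "degradome", "reads")


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx, extra)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


class CapacityError(ValueError):
    """More miRNAs requested than the transcript set can host target sites for."""


def generate_reference(
    n_transcripts: int,
    n_mirnas: int,
    seed: int,
    transcript_length: tuple[int, int] = (400, 1200),
    mirna_length: int = 21,
    sites_per_transcript: int = 1,
    n_novel_hairpins: int = 0,
    n_terms: int = 30,
    terms_per_gene: tuple[int, int] = (1, 4),
) -> ReferenceBundle:
    """Build a deterministic synthetic reference.

    Each miRNA i gets (a) a hairpin precursor containing its mature on the 5'
    arm and (b) one exactly complementary target site embedded in transcript i
    (one site per transcript by default).  Optionally, ``n_novel_hairpins``
    extra hairpins are embedded in transcripts without catalog entries, to
    exercise novel-miRNA discovery.  Annotation terms (GO-like and KEGG-like,
    with top-level classes) are assigned to every transcript.
    """
    if n_transcripts < 1 or n_mirnas < 1:
        raise ValueError("counts must be >= 1")
    capacity = n_transcripts * sites_per_transcript
    if n_mirnas > capacity:
        raise CapacityError(
            f"{n_mirnas} miRNAs exceed target-site capacity "
            f"{capacity} ({n_transcripts} transcripts x {sites_per_transcript})"
        )
    rng = _rng(seed, "reference")

    transcripts: dict[str, str] = {}
    tids = [f"TXG{i + 1:05d}-1" for i in range(n_transcripts)]
    lengths = rng.integers(transcript_length[0], transcript_length[1] + 1, n_transcripts)
    for tid, ln in zip(tids, lengths):
        transcripts[tid] = _random_seq(rng, int(ln))

    species = ("tds", "tae", "osa", "ata", "bdi")
    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    target_sites: dict[str, tuple[str, int, int, int]] = {}
    for i in range(n_mirnas):
        sp = species[int(rng.integers(len(species)))]
        mid = f"{sp}-miR{9000 + i}"
        mat = _random_seq(rng, mirna_length)
        matures[mid] = mat
        # hairpin: 5' flank + mature (5p arm) + loop + revcomp(mature) + 3' flank
        loop = _random_seq(rng, int(rng.integers(4, 9)))
        flank5 = _random_seq(rng, int(rng.integers(5, 16)))
        flank3 = _random_seq(rng, int(rng.integers(5, 16)))
        precursors[mid] = flank5 + mat + loop + revcomp(mat) + flank3

        # plant an exactly complementary site in transcript i (sense strand)
        tid = tids[i % n_transcripts]
        seq = transcripts[tid]
        site = revcomp(mat)
        lo, hi = 30, len(seq) - mirna_length - 30
        start0 = int(rng.integers(lo, hi))
        transcripts[tid] = seq[:start0] + site + seq[start0 + mirna_length:]
        start, end = start0 + 1, start0 + mirna_length  # 1-based inclusive
        cleavage = end - 9  # transcript base paired to miRNA position 10
        target_sites[mid] = (tid, start, end, cleavage)

    novel_hairpins: dict[str, tuple[str, str, int]] = {}
    for k in range(n_novel_hairpins):
        tid = tids[(n_mirnas + k) % n_transcripts]
        seq = transcripts[tid]
        mat = _random_seq(rng, mirna_length)
        loop = _random_seq(rng, 6)
        hp = mat + loop + revcomp(mat)
        start0 = len(seq) // 2
        transcripts[tid] = seq[:start0] + hp + seq[start0 + len(hp):]
        novel_hairpins[f"novel-{k + 1}"] = (tid, mat, start0 + 1)

    go_terms = {f"GO:{7000000 + i}": (f"synthetic process {i}", ns)
                for i, ns in zip(range(n_terms // 2), _cycle(("BP", "MF", "CC"), n_terms // 2))}
    kegg_classes = (
        "Metabolism", "Genetic Information Processing", "Environmental Information Processing",
        "Cellular Processes", "Organismal Systems",
    )
    ko_terms = {f"ko{10000 + i}": (f"synthetic pathway {i}", kegg_classes[i % len(kegg_classes)])
                for i in range(n_terms - n_terms // 2)}
    term_info = {**go_terms, **ko_terms}
    term_ids = sorted(term_info)
    annotation: dict[str, set[str]] = {}
    for tid in tids:
        k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
        annotation[tid] = set(rng.choice(term_ids, size=min(k, len(term_ids)), replace=False))

    ref = ReferenceBundle(
        transcripts=transcripts,
        mirna_matures=matures,
        mirna_precursors=precursors,
        annotation=annotation,
        gene_lengths={t: len(s) for t, s in transcripts.items()},
        target_sites=target_sites,
        novel_hairpins=novel_hairpins,
        term_info=term_info,
    )
    ref.validate()
    return ref


def _cycle(items: Sequence[str], n: int):
    return [items[i % len(items)] for i in range(n)]


def plant_truth(
    ref: ReferenceBundle,
    n_modules: int,
    effect_size: float = 3.0,
    treatments: Sequence[str] = ("WS", "HS", "WH"),
    nb_dispersion: float = 0.1,
    library_size_range: tuple[int, int] = (800_000, 1_200_000),
    seed: int = 0,
) -> SyntheticTruth:
    """Choose antagonistic modules among the reference's planted target sites.

    Each module picks one miRNA with a known site, a stress treatment, and a
    signed log2 effect of magnitude ``effect_size`` (sign random); its target
    gene receives the opposite-signed effect (coupling -1) in the same
    stressed condition.
    """
    rng = _rng(seed, "truth")
    mirna_ids = sorted(ref.target_sites)
    if n_modules > len(mirna_ids):
        raise ValueError("more modules than miRNAs with planted sites")
    chosen = rng.choice(mirna_ids, size=n_modules, replace=False)
    de_mirnas: dict[str, tuple[str, float]] = {}
    de_genes: dict[str, tuple[str, float]] = {}
    modules: list[tuple[str, str, int, int]] = []
    for mid in chosen:
        tid, start, end, cleavage = ref.target_sites[mid]
        tr = str(rng.choice(np.asarray(treatments)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        de_mirnas[mid] = (tr, sign * effect_size)
        de_genes[tid] = (tr, -sign * effect_size)
        modules.append((mid, tid, cleavage, -1))
    truth = SyntheticTruth(
        planted_de_mirnas=de_mirnas,
        planted_de_genes=de_genes,
        planted_modules=modules,
        nb_dispersion=nb_dispersion,
        library_size_range=library_size_range,
        seed=seed,
    )
    truth.validate_against(ref)
    return truth


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draw via gamma-Poisson; dispersion 0 is Poisson."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _simulate_counts(
    feature_ids: Sequence[str],
    baselines: np.ndarray,
    planted: Mapping[str, tuple[str, float]],
    design: ExperimentDesign,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> CountMatrix:
    samples = design.sample_names()
    table = design.sample_table(samples)
    lo, hi = truth.library_size_range
    libsizes = rng.integers(lo, hi + 1, size=len(samples)).astype(float)
    out = np.zeros((len(feature_ids), len(samples)), dtype=np.int64)
    effects = np.zeros(len(feature_ids))
    idx = {f: i for i, f in enumerate(feature_ids)}
    for j, s in enumerate(samples):
        treatment = table.loc[s, "treatment"]
        effects[:] = 0.0
        for f, (tr, eff) in planted.items():
            if tr == treatment and f in idx:
                effects[idx[f]] = eff
        mean = baselines * (2.0 ** effects) * (libsizes[j] / 1e6)
        out[:, j] = _nb_counts(rng, mean, truth.nb_dispersion)
    counts = pd.DataFrame(out, index=list(feature_ids), columns=samples)
    return CountMatrix(counts, pd.Series(libsizes, index=samples))


def simulate_srna_counts(
    ref: ReferenceBundle,
    design: ExperimentDesign,
    truth: SyntheticTruth,
    baseline_log_mean: float = math.log(200.0),
    baseline_log_sd: float = 1.0,
) -> CountMatrix:
    """miRNA count matrix over the design (baselines in counts-per-million units).

    Planted DE miRNAs have mean = baseline x 2^effect in samples of their
    stressed treatment (all genotypes/time-points).
    """
    truth.validate_against(ref)
    rng = _rng(truth.seed, "srna")
    ids = sorted(ref.mirna_matures)
    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, len(ids)))
    return _simulate_counts(ids, baselines, truth.planted_de_mirnas, design, truth, rng)


def simulate_expression_matrix(
    ref: ReferenceBundle,
    design: ExperimentDesign,
    truth: SyntheticTruth,
    baseline_log_mean: float = math.log(150.0),
    baseline_log_sd: float = 1.0,
) -> CountMatrix:
    """Gene-level count matrix; planted module genes carry the coupled effect."""
    truth.validate_against(ref)
    rng = _rng(truth.seed, "genes")
    ids = sorted(ref.transcripts)
    baselines = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, len(ids)))
    return _simulate_counts(ids, baselines, truth.planted_de_genes, design, truth, rng)


def srna_length_histogram(
    n_reads: int, seed: int, modes: tuple[int, int] = (21, 24)
) -> pd.Series:
    """Read-length draw with the two-peak pattern at 21 and 24 nt."""
    rng = _rng(seed, "reads", extra=1)
    lengths = np.arange(18, 27)
    weights = np.full(len(lengths), 0.04)
    weights[lengths == modes[0]] = 0.42
    weights[lengths == modes[1]] = 0.30
    weights /= weights.sum()
    draw = rng.choice(lengths, size=n_reads, p=weights)
    return pd.Series(draw).value_counts().sort_index()


@dataclass
class DegradomeTag:
    """One simulated degradome tag (exact transcript substring)."""

    sequence: str
    transcript_id: str
    position: int  # 1-based 5' end on the source transcript


def simulate_degradome_tags(
    ref: ReferenceBundle,
    truth: SyntheticTruth,
    depth: int,
    seed: int,
    signal_fraction: float = 0.3,
    tag_lengths: tuple[int, int] = (20, 21),
    library: int = 0,
) -> list[DegradomeTag]:
    """Simulate one degradome library of ``depth`` tags.

    ``signal_fraction`` of the depth is split equally among the planted
    modules and placed exactly at their cleavage positions; the rest is
    uniform background over transcripts and positions.  Tags are exact
    20-21 nt substrings of their source transcripts (truncated windows near
    the 3' end are redrawn).  ``library`` indexes independent libraries under
    the same seed.
    """
    if depth == 0:
        return []
    rng = _rng(seed, "degradome", extra=library)
    tids = sorted(ref.transcripts)
    tags: list[DegradomeTag] = []

    n_signal = int(round(depth * signal_fraction)) if truth.planted_modules else 0
    per_module = n_signal // max(len(truth.planted_modules), 1) if n_signal else 0
    for mid, tid, cleavage, _sign in truth.planted_modules:
        seq = ref.transcripts[tid]
        for _ in range(per_module):
            ln = int(rng.integers(tag_lengths[0], tag_lengths[1] + 1))
            if cleavage - 1 + ln > len(seq):
                ln = len(seq) - cleavage + 1
            tags.append(DegradomeTag(seq[cleavage - 1:cleavage - 1 + ln], tid, cleavage))

    n_background = depth - len(tags)
    for _ in range(n_background):
        tid = tids[int(rng.integers(len(tids)))]
        seq = ref.transcripts[tid]
        ln = int(rng.integers(tag_lengths[0], tag_lengths[1] + 1))
        pos0 = int(rng.integers(0, len(seq) - ln + 1))
        tags.append(DegradomeTag(seq[pos0:pos0 + ln], tid, pos0 + 1))
    return tags


def simulate_srna_reads(
    ref: ReferenceBundle,
    n_reads: int,
    seed: int,
    variant_rate: float = 0.15,
    novel_fraction: float = 0.1,
    background_fraction: float = 0.15,
) -> list[str]:
    """Simulate an adapter-trimmed small-RNA read multiset.

    Reads are drawn from catalog matures (Zipf-weighted abundances), with a
    ``variant_rate`` share carrying a 3'/5' length shift (<= 2 nt, trims, or
    extensions taken from the precursor) or one internal substitution; a
    ``novel_fraction`` share comes from planted novel hairpin matures; the
    background is random sequence with lengths spanning 15-30 nt so the
    length filter has something to remove.
    """
    rng = _rng(seed, "reads")
    matures = sorted(ref.mirna_matures)
    weights = 1.0 / np.arange(1, len(matures) + 1)
    weights /= weights.sum()
    novel = sorted(ref.novel_hairpins)
    reads: list[str] = []
    for _ in range(n_reads):
        u = rng.random()
        if novel and u < novel_fraction:
            _, mat, _ = ref.novel_hairpins[novel[int(rng.integers(len(novel)))]]
            reads.append(mat)
        elif u < novel_fraction + background_fraction:
            reads.append(_random_seq(rng, int(rng.integers(15, 31))))
        else:
            mid = matures[int(rng.choice(len(matures), p=weights))]
            seq = ref.mirna_matures[mid]
            if rng.random() < variant_rate:
                seq = _variant_read(rng, seq, ref.mirna_precursors.get(mid))
            reads.append(seq)
    return reads


def _variant_read(rng: np.random.Generator, mature: str, precursor: str | None) -> str:
    kind = int(rng.integers(3))
    if kind == 0:  # 3' trim
        k = int(rng.integers(1, 3))
        return mature[:-k]
    if kind == 1:  # 5' trim
        k = int(rng.integers(1, 3))
        return mature[k:]
    pos = int(rng.integers(2, len(mature) - 2))
    alt = str(rng.choice([b for b in "ACGT" if b != mature[pos]]))
    return mature[:pos] + alt + mature[pos + 1:]


def evaluate_recovery(
    modules: pd.DataFrame, truth: SyntheticTruth, gene_of=lambda t: t.rsplit("-", 1)[0]
) -> dict[str, float]:
    """Score a reported module table against the planted truth.

    A planted module is recovered when a reported row matches its miRNA,
    gene, stressed treatment (the contrast's first level) and the expected
    antagonistic pattern.  Spurious rate = reported (miRNA, gene, treatment)
    triples not planted / all reported triples.
    """
    expected = {}
    for mid, tid, _pos, _sign in truth.planted_modules:
        tr, eff = truth.planted_de_mirnas[mid]
        pattern = "miRNA-up/target-down" if eff > 0 else "miRNA-down/target-up"
        expected[(mid, gene_of(tid), tr)] = pattern

    reported: dict[tuple[str, str, str], set[str]] = {}
    antagonistic = modules[modules["pattern"].str.startswith("miRNA-")]
    for row in antagonistic.itertuples():
        treatment = str(row.contrast).split("_vs_")[0].split("|")[-1]
        key = (row.mirna, row.gene, treatment)
        reported.setdefault(key, set()).add(row.pattern)

    recovered = sum(
        1 for key, pat in expected.items() if pat in reported.get(key, set())
    )
    spurious = sum(1 for key in reported if key not in expected)
    n_exp, n_rep = len(expected), len(reported)
    return {
        "n_planted": n_exp,
        "n_reported": n_rep,
        "recall": recovered / n_exp if n_exp else float("nan"),
        "spurious_rate": spurious / n_rep if n_rep else 0.0,
    }
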