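"""Core in-memory containers shared across the pipeline.

The experimental layout is a factorial design over genotype (stress-tolerant
"TL" vs stress-sensitive "SL"), treatment (control CG, water-deficit WS, heat
HS, combined WH), sampling time-point (days post-anthesis) and biological
replicate.  Every sample name encodes its design cell and parses back
losslessly, e.g. ``TL5_CG_1`` = tolerant genotype, 5 DPA, control, replicate 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SAMPLE_RE = re.compile(r"^([A-Za-z]+?)(\d+)_([A-Za-z0-9]+)_(\d+)$")


@dataclass(frozen=True)
class SampleName:
    """A parsed sample label tying a column to its design cell."""

    genotype: str
    timepoint: int
    treatment: str
    replicate: int

    def __str__(self) -> str:
        return f"{self.genotype}{self.timepoint}_{self.treatment}_{self.replicate}"

    @classmethod
    def parse(cls, name: str) -> "SampleName":
        m = SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(f"sample name {name!r} does not encode a design cell")
        g, t, tr, r = m.groups()
        return cls(genotype=g, timepoint=int(t), treatment=tr, replicate=int(r))


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design: genotypes x treatments x time-points x replicates."""

    genotypes: tuple[str, ...] = ("TL", "SL")
    treatments: tuple[str, ...] = ("CG", "WS", "HS", "WH")
    timepoints: tuple[int, ...] = (5, 15, 25, 35, 45)
    replicates: int = 3

    def __post_init__(self) -> None:
        for fac, labels in (("genotypes", self.genotypes), ("treatments", self.treatments)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels in {fac}: {labels}")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError(f"duplicate timepoints: {self.timepoints}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.genotypes) * len(self.treatments) * len(self.timepoints) * self.replicates
        )

    def sample_names(self) -> list[str]:
        """All sample labels in deterministic (genotype, timepoint, treatment, rep) order."""
        return [
            str(SampleName(g, tp, tr, r + 1))
            for g in self.genotypes
            for tp in self.timepoints
            for tr in self.treatments
            for r in range(self.replicates)
        ]

    def sample_table(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else self.sample_names()
        rows = [SampleName.parse(n) for n in names]
        return pd.DataFrame(
            {
                "sample": names,
                "genotype": [r.genotype for r in rows],
                "timepoint": [r.timepoint for r in rows],
                "treatment": [r.treatment for r in rows],
                "replicate": [r.replicate for r in rows],
            }
        ).set_index("sample")


def parse_samples(names: Iterable[str]) -> pd.DataFrame:
    """Design-factor table for arbitrary sample labels (index = sample)."""
    return ExperimentDesign().sample_table(names)


@dataclass
class CountMatrix:
    """Feature x sample table of non-negative integer counts.

    ``library_sizes`` defaults to column sums; an override models sequencing
    depth larger than the features retained in the matrix.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns).astype(float)
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some samples")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def sample_table(self) -> pd.DataFrame:
        return parse_samples(self.samples)

    def subset_samples(self, mask_or_names) -> "CountMatrix":
        sub = self.counts.loc[:, mask_or_names]
        return CountMatrix(sub, self.library_sizes.loc[sub.columns])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, library_sizes: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, library_sizes)


@dataclass
class FPKMMatrix:
    """Fragments per kilobase of transcript per million mapped fragments."""

    values: pd.DataFrame
    lengths: pd.Series  # feature length in nt

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.values.index).astype(float)
        if self.lengths.isna().any():
            raise ValueError("feature lengths missing for some features")
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


@dataclass
class ReferenceBundle:
    """Synthetic or loaded reference: transcripts, miRNA catalog, annotation.

    ``target_sites`` records, for each miRNA with a planted near-complementary
    site, the transcript it sits in and the expected cleavage coordinate (the
    transcript base opposite miRNA position 10, 1-based inclusive coordinates).
    """

    transcripts: dict[str, str]
    mirna_matures: dict[str, str]
    mirna_precursors: dict[str, str]
    annotation: dict[str, set[str]] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    target_sites: dict[str, tuple[str, int, int, int]] = field(default_factory=dict)
    # mirna_id -> (transcript_id, site_start, site_end, cleavage_pos), 1-based inclusive
    novel_hairpins: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    # novel_id -> (transcript_id, mature_sequence, mature_start)
    term_info: dict[str, tuple[str, str]] = field(default_factory=dict)
    # term -> (name, namespace / top-level class)

    def __post_init__(self) -> None:
        if not self.gene_lengths:
            self.gene_lengths = {k: len(v) for k, v in self.transcripts.items()}

    def validate(self) -> None:
        for mid, mat in self.mirna_matures.items():
            if not (18 <= len(mat) <= 26):
                raise ValueError(f"mature {mid} length {len(mat)} outside 18-26 nt")
        for pid, pre in self.mirna_precursors.items():
            mat = self.mirna_matures.get(pid)
            if mat is not None and mat not in pre:
                raise ValueError(f"mature {pid} is not a substring of its precursor")
        for tid, seq in self.transcripts.items():
            if len(seq) < 200:
                raise ValueError(f"transcript {tid} shorter than 200 nt")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: planted effects and regulatory modules.

    ``planted_modules`` holds (miRNA id, transcript id, cleavage position,
    coupling sign); coupling -1 means the transcript's gene receives the
    opposite-signed log2 effect of its miRNA partner (antagonistic module).
    """

    planted_de_mirnas: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_modules: list[tuple[str, str, int, int]] = field(default_factory=list)
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        for m, t, pos, sign in self.planted_modules:
            if sign not in (-1, 1):
                raise ValueError(f"coupling sign must be +1/-1, got {sign}")

    def validate_against(self, ref: ReferenceBundle) -> None:
        for m, t, pos, sign in self.planted_modules:
            if m not in ref.mirna_matures:
                raise ValueError(f"planted module references unknown miRNA {m}")
            if t not in ref.transcripts:
                raise ValueError(f"planted module references unknown transcript {t}")
        for m in self.planted_de_mirnas:
            if m not in ref.mirna_matures:
                raise ValueError(f"planted DE miRNA {m} not in reference")
        for g in self.planted_de_genes:
            if g not in ref.transcripts:
                raise ValueError(f"planted DE gene {g} not in reference")
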