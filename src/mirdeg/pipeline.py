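"""Configuration-driven orchestration of the full synthetic-mode pipeline.

``run_all`` executes simulate -> mirnas -> de -> degradome -> integrate ->
enrich on a seeded synthetic dataset, writing every stage's tables under the
output directory plus a manifest recording parameters, derived per-stage
seeds and SHA-256 hashes of all outputs (idempotent for a fixed config).
Integrated layers (transcriptome, degradome) are simulated at one time-point,
mirroring a design where sRNA profiling spans the full factorial but mRNA and
degradome libraries are made at a single sampling point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import io, synthio
from .containers import CountMatrix, ExperimentDesign
from .degradome import build_tag_index, call_targets, events_table, find_targets, map_tags
from .enrichment import hypergeom_enrich, kegg_class_distribution
from .expression_stats import nb_exact_de, normalize_cpm, ttest_pairwise
from .integration import antagonistic_modules, export_network, join_evidence
from .mirna_discovery import presence_partition


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run (YAML round-trippable)."""

    outdir: str = "mirdeg_out"
    seed: int = 1

    # design
    genotypes: tuple[str, ...] = ("TL", "SL")
    treatments: tuple[str, ...] = ("CG", "WS", "HS", "WH")
    timepoints: tuple[int, ...] = (5,)
    replicates: int = 3

    # generator
    n_transcripts: int = 2000
    n_mirnas: int = 200
    n_modules: int = 50
    effect_size: float = 3.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    degradome_depth: int = 100_000
    degradome_signal_fraction: float = 0.3

    # thresholds
    alpha: float = 0.05
    floor: float = 0.001
    max_penalty: float = 4.5
    presence_cpm: float = 1.0
    shift_window: int = 1
    category_max: int = 4
    condition_matched: bool = False
    mirna_test: str = "ttest"   # miRNA layer contrast test
    gene_test: str = "nbexact"  # gene layer contrast test
    scan_mode: str = "seed"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(f.default, tuple) else v
        return cls(**kwargs)

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            genotypes=tuple(self.genotypes), treatments=tuple(self.treatments),
            timepoints=tuple(self.timepoints), replicates=self.replicates,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _de_contrasts(
    counts: CountMatrix, cfg: PipelineConfig, test: str
) -> pd.DataFrame:
    """Stress-vs-control and genotype contrasts over the design."""
    table = counts.sample_table()
    frames = []
    control = cfg.treatments[0]
    for g in cfg.genotypes:
        sub = counts.subset_samples(table.index[table["genotype"] == g])
        st = sub.sample_table()
        groups = st["treatment"].values
        for tr in cfg.treatments[1:]:
            name = f"{tr}_vs_{control}|{g}"
            if test == "ttest":
                frames.append(ttest_pairwise(sub, groups, tr, control,
                                             floor=cfg.floor, alpha=cfg.alpha, contrast=name))
            elif test == "nbexact":
                frames.append(nb_exact_de(sub, groups, tr, control,
                                          floor=cfg.floor, alpha=cfg.alpha, contrast=name))
            else:
                raise ValueError(f"unknown test {test!r}")
    if len(cfg.genotypes) >= 2:
        ga, gb = cfg.genotypes[0], cfg.genotypes[1]
        for tr in cfg.treatments:
            sel = table.index[table["treatment"] == tr]
            sub = counts.subset_samples(sel)
            groups = sub.sample_table()["genotype"].values
            name = f"{ga}_vs_{gb}|{tr}"
            if test == "ttest":
                frames.append(ttest_pairwise(sub, groups, ga, gb,
                                             floor=cfg.floor, alpha=cfg.alpha, contrast=name))
            else:
                frames.append(nb_exact_de(sub, groups, ga, gb,
                                          floor=cfg.floor, alpha=cfg.alpha, contrast=name))
    return pd.concat(frames, ignore_index=True)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to manifest.json)."""
    out = io.ensure_dir(cfg.outdir)
    design = cfg.design()
    manifest: dict = {
        "config": cfg.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stage_seeds": {
            "reference": cfg.seed, "truth": cfg.seed,
            "srna": cfg.seed, "genes": cfg.seed, "degradome": cfg.seed,
        },
        "outputs": {},
    }

    # --- simulate ---------------------------------------------------------
    ref = synthio.generate_reference(cfg.n_transcripts, cfg.n_mirnas, cfg.seed)
    truth = synthio.plant_truth(
        ref, cfg.n_modules, effect_size=cfg.effect_size,
        treatments=tuple(cfg.treatments[1:]), nb_dispersion=cfg.nb_dispersion,
        library_size_range=tuple(cfg.library_size_range), seed=cfg.seed,
    )
    mirna_counts = synthio.simulate_srna_counts(ref, design, truth)
    gene_counts = synthio.simulate_expression_matrix(ref, design, truth)

    io.write_fasta(ref.transcripts, out / "transcripts.fasta")
    io.write_fasta(ref.mirna_matures, out / "mirna_matures.fasta")
    io.write_fasta(ref.mirna_precursors, out / "mirna_precursors.fasta")
    io.write_annotation(ref.annotation, out / "annotation.tsv")
    io.write_term_info(ref.term_info, out / "terms.tsv")
    mirna_counts.to_tsv(out / "mirna_counts.tsv")
    gene_counts.to_tsv(out / "gene_counts.tsv")
    truth_rows = [
        {"mirna": m, "transcript": t, "cleavage_pos": p, "coupling": s,
         "treatment": truth.planted_de_mirnas[m][0],
         "mirna_effect": truth.planted_de_mirnas[m][1]}
        for m, t, p, s in truth.planted_modules
    ]
    io.write_table(pd.DataFrame(truth_rows), out / "planted_modules.tsv")

    # --- mirnas: presence partitions over treatments ----------------------
    regions = presence_partition(mirna_counts, "treatment",
                                 presence_cpm=cfg.presence_cpm)
    venn = pd.DataFrame(
        [{"region": "&".join(sorted(k)), "count": v} for k, v in sorted(
            regions.items(), key=lambda kv: ("&".join(sorted(kv[0])))
        )]
    )
    io.write_table(venn, out / "mirna_presence_venn.tsv")

    # --- de ----------------------------------------------------------------
    mirna_de = _de_contrasts(mirna_counts, cfg, cfg.mirna_test)
    gene_de = _de_contrasts(gene_counts, cfg, cfg.gene_test)
    gene_de["feature"] = [t.rsplit("-", 1)[0] for t in gene_de["feature"]]
    io.write_table(mirna_de, out / "mirna_de.tsv")
    io.write_table(gene_de, out / "gene_de.tsv")

    # --- degradome ---------------------------------------------------------
    alignments = find_targets(ref.mirna_matures, ref.transcripts,
                              max_penalty=cfg.max_penalty, mode=cfg.scan_mode)
    profiles = {}
    tag_index = build_tag_index(ref.transcripts)
    for li, tr in enumerate(cfg.treatments):
        lib = f"deg_{tr}"
        tags = synthio.simulate_degradome_tags(
            ref, truth, cfg.degradome_depth, cfg.seed,
            signal_fraction=cfg.degradome_signal_fraction, library=li,
        )
        profiles[lib] = map_tags([t.sequence for t in tags], ref.transcripts,
                                 index=tag_index)
    events = call_targets(alignments, profiles,
                          shift_window=cfg.shift_window, category_max=cfg.category_max)
    io.write_table(events_table(events), out / "cleavage_events.tsv")

    # --- integrate ---------------------------------------------------------
    pairs, audit = join_evidence(
        mirna_de, gene_de, events, alpha=cfg.alpha,
        condition_matched=cfg.condition_matched,
    )
    modules = antagonistic_modules(pairs)
    io.write_table(pairs, out / "regulatory_pairs.tsv")
    io.write_table(modules, out / "modules.tsv")
    degrees = export_network(pairs, sif_path=out / "network.sif",
                             tsv_path=out / "network_edges.tsv")
    io.write_table(degrees, out / "network_degrees.tsv")
    manifest["join_audit"] = dataclasses.asdict(audit)

    # --- enrich ------------------------------------------------------------
    module_genes = sorted(set(modules["transcript"]))
    enr = hypergeom_enrich(module_genes, ref.annotation, term_info=ref.term_info)
    io.write_table(enr, out / "module_enrichment.tsv")
    kegg_ns = {ns for _, ns in ref.term_info.values() if not ns in ("BP", "MF", "CC")}
    dist = kegg_class_distribution(module_genes, ref.annotation, ref.term_info,
                                   namespaces=kegg_ns)
    io.write_table(dist.table, out / "module_kegg_classes.tsv")

    # --- recovery vs truth + manifest --------------------------------------
    recovery = synthio.evaluate_recovery(modules, truth)
    manifest["recovery"] = recovery
    cfg_dict = cfg.to_dict()
    cfg_dict.pop("outdir")  # implied by the file's location; keeps runs comparable
    io.dump_config(cfg_dict, out / "config.yaml")
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def require_inputs(*paths) -> None:
    """Fail fast with the offending path when a stage input is missing."""
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
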