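"""Small-RNA processing: length filter, variant-aware matching, novel discovery.

Simulates a read set, collapses it, assigns reads to the known catalog
(encoding end-shifts and substitutions in the record ids), discovers novel
miRNAs from hairpin-forming unmatched reads, and partitions presence across
treatments (Venn regions).
"""

from mirdeg import ExperimentDesign, generate_reference, plant_truth
from mirdeg.mirna_discovery import (
    assign_groups,
    discover_novel_mirnas,
    match_known_mirnas,
    preprocess_reads,
    presence_partition,
)
from mirdeg.synthio import simulate_srna_counts, simulate_srna_reads

ref = generate_reference(120, 25, seed=7, n_novel_hairpins=2)
reads = simulate_srna_reads(ref, 4000, seed=7)

lib = preprocess_reads(reads, sample="TL5_CG_1")
print(f"{lib.total_clean} clean reads (18-26 nt), {len(lib.unique_reads)} unique")

records = match_known_mirnas(lib, ref.mirna_matures, ref.mirna_precursors)
matched_seqs = {r.sequence for r in records}
variants = [r for r in records if r.variant]
print(f"{len(records)} known records, {len(variants)} variant-matched, e.g.:")
for r in variants[:3]:
    print(f"  {r.id}  (variant suffix encodes the end-shift / substitution)")

unmatched = {s: n for s, n in lib.unique_reads.items() if s not in matched_seqs}
novel = discover_novel_mirnas(unmatched, ref.transcripts, sample=lib.sample,
                              max_candidates=20)
assign_groups(records + novel)
print(f"{len(novel)} novel (G5) miRNAs pass the hairpin criteria "
      f"(>=16 mature bases paired to the star, loop >= 3 nt)")

design = ExperimentDesign(genotypes=("TL",), timepoints=(5,), replicates=3)
truth = plant_truth(ref, 6, seed=7)
cm = simulate_srna_counts(ref, design, truth)
regions = presence_partition(cm, "treatment", presence_cpm=1.0)
center = regions[frozenset({"CG", "WS", "HS", "WH"})]
print(f"\nVenn center (expressed under all four treatments at CPM>=1 in >=2 reps): "
      f"{center} miRNAs of {sum(regions.values())} total")
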