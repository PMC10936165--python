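#!/usr/bin/env python
"""Build the synthetic study fixtures.

Generates the default synthetic genome (120 genes, three planted
dispensable regions of 12, 8 and 5 genes), its divergent reference
proteome (5% residue substitutions), the essentiality/orthology ground
truth, and the paired toy metabolic model, and writes them under
results/fixtures/ in the standard formats (GenBank, GFF3+FASTA, FASTA,
TSV, model JSON).
"""

from pathlib import Path

from genoslim.pipeline import cmd_synth
from genoslim.synthetic import SynthesisSpec

ROOT = Path(__file__).resolve().parents[1]

STUDY_SPEC = SynthesisSpec(
    n_genes=120,
    mean_gene_len=300,
    intergenic_len=50,
    essential_fraction=0.3,
    planted_regions=((20, 31), (55, 62), (90, 94)),
    mutation_rate=0.05,
    seed=42,
)


def main() -> None:
    outdir = cmd_synth(STUDY_SPEC, ROOT / "results" / "fixtures", force=True)
    print(f"wrote synthetic study fixtures to {outdir}")
    print(f"  genes: {STUDY_SPEC.n_genes}, planted regions: {STUDY_SPEC.planted_regions}")
    print("  files: genome.gb genome.gff3 genome.fna reference_proteome.faa "
          "essentiality_truth.tsv model.json manifest.json")


if __name__ == "__main__":
    main()
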