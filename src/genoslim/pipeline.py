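"""High-level pipeline commands.

Each command reads/writes the formats defined in
:mod:`genoslim.io_formats`, performs one pipeline stage, and leaves a
machine-readable ``manifest.json`` (inputs, parameter values, seeds,
tool version) sufficient to re-run the stage bit-identically for
deterministic stages and distribution-identically for seeded ones.

The numbered scripts under ``analysis/`` and the ``genoslim`` CLI are
both thin layers over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import GenomeAnnotation
from .cas3 import (
    DEFAULT_MAX_AMPLICON,
    band_matrix,
    deletion_length_histogram,
    infer_deletion_bounds,
    make_tiling_panel,
    max_deletion_window,
    simulate_deletion_library,
)
from .errors import ValidationError
from .homology import (
    DEFAULT_E_CUTOFF,
    ESSENTIAL,
    EssentialityMap,
    reciprocal_best_hits,
    transfer_essentiality,
)
from .io_formats import (
    read_annotation,
    read_fasta,
    read_locus_list,
    write_annotation,
    write_essentiality,
    write_fasta,
    write_model,
    write_regions_bed,
)
from .regions import SearchConfig, enumerate_regions, region_length_footnote
from .synthetic import (
    SynthesisSpec,
    generate_genome,
    generate_reference_proteome,
    generate_toy_model,
)

logger = logging.getLogger(__name__)


def _write_manifest(outdir: Path, command: str, params: dict, outputs: list[str]) -> None:
    manifest = {
        "tool": "genoslim",
        "version": __version__,
        "command": command,
        "parameters": params,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")


def _prepare_outdir(outdir, force: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


# ---------------------------------------------------------------------------


def cmd_synth(spec: SynthesisSpec, outdir, force: bool = False, uptake_bound: float = 10.0) -> Path:
    """Write a complete synthetic fixture set: genome (GenBank and
    GFF3+FASTA), mutated reference proteome, essentiality/orthology
    truth, and a toy metabolic model."""
    outdir = _prepare_outdir(outdir, force)
    ann, truth = generate_genome(spec)
    proteome, ortholog_truth = generate_reference_proteome(ann, spec.mutation_rate, spec.seed)
    model = generate_toy_model(ann, truth, uptake_bound=uptake_bound, seed=spec.seed)

    write_annotation(ann, outdir / "genome.gb", "genbank")
    write_annotation(ann, outdir / "genome.gff3", "gff3", fasta=outdir / "genome.fna")
    write_fasta(proteome, outdir / "reference_proteome.faa")
    truth_with_refs = EssentialityMap(dict(truth.labels), dict(ortholog_truth))
    write_essentiality(truth_with_refs, outdir / "essentiality_truth.tsv")
    write_model(model, outdir / "model.json")

    outputs = [
        "genome.gb",
        "genome.gff3",
        "genome.fna",
        "reference_proteome.faa",
        "essentiality_truth.tsv",
        "model.json",
    ]
    _write_manifest(outdir, "synth", dataclasses.asdict(spec) | {"uptake_bound": uptake_bound}, outputs)
    return outdir


def reference_essentials_from_truth(truth_path) -> set[str]:
    """Reference-side essential ids implied by a fixture truth table."""
    df = pd.read_csv(truth_path, sep="\t")
    return set(df.loc[df["label"] == ESSENTIAL, "provenance"].dropna())


def cmd_map_essentiality(
    annotation_path,
    reference_proteome_path,
    essential_list,
    out_tsv,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    annotation_format: str = "genbank",
    fasta=None,
) -> EssentialityMap:
    """Transfer reference essentiality onto an annotation via RBH.

    ``essential_list`` may be a path to a locus list or an in-memory
    set of reference ids.
    """
    ann = read_annotation(annotation_path, annotation_format, fasta=fasta)
    reference = read_fasta(reference_proteome_path)
    essentials = (
        set(essential_list)
        if isinstance(essential_list, (set, frozenset))
        else read_locus_list(essential_list)
    )
    queries = {f.locus_tag: f.protein for f in ann.features if f.protein}
    logger.info(
        "mapping essentiality: %d queries vs %d reference proteins, e-value cutoff %g",
        len(queries),
        len(reference),
        e_cutoff,
    )
    rbh = reciprocal_best_hits(queries, reference, e_cutoff)
    ess = transfer_essentiality(ann, rbh, essentials, reference_ids=set(reference))
    write_essentiality(ess, out_tsv)
    outdir = Path(out_tsv).parent
    _write_manifest(
        outdir,
        "map-essentiality",
        {
            "annotation": str(annotation_path),
            "reference_proteome": str(reference_proteome_path),
            "e_cutoff": e_cutoff,
            "n_mapped": len(rbh),
        },
        [Path(out_tsv).name],
    )
    return ess


def regions_table(ann: GenomeAnnotation, regions) -> pd.DataFrame:
    """Report mirroring the published dispensable-region table layout,
    with both start-site length conventions alongside the raw span."""
    rows = []
    for r in regions:
        rows.append(
            {
                "rank": r.rank,
                "first_locus": r.first_locus,
                "last_locus": r.last_locus,
                "start_coord": r.start_coord,
                "end_coord": r.end_coord,
                "n_genes": r.n_genes,
                "length_span_bp": r.length_span,
                "length_start_to_start_bp": region_length_footnote(
                    ann, r.first_locus, r.last_locus, strand_aware=True
                ),
                "length_start_to_start_naive_bp": region_length_footnote(
                    ann, r.first_locus, r.last_locus, strand_aware=False
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "first_locus",
            "last_locus",
            "start_coord",
            "end_coord",
            "n_genes",
            "length_span_bp",
            "length_start_to_start_bp",
            "length_start_to_start_naive_bp",
        ],
    )


def cmd_find_regions(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    model,
    outdir,
    cfg: SearchConfig = SearchConfig(),
    force: bool = False,
) -> pd.DataFrame:
    """Run the region search and write the ranked table and BED."""
    outdir = _prepare_outdir(outdir, force)
    regions = enumerate_regions(ann, ess, model, cfg)
    table = regions_table(ann, regions)
    table.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    write_regions_bed(regions, outdir / "regions.bed", sequence_id=ann.sequence_id)
    if not regions:
        logger.warning(
            "no dispensable region of span >= %d bp exists under the given "
            "essentiality and growth constraints",
            cfg.min_region_len,
        )
    _write_manifest(
        outdir,
        "find-regions",
        dataclasses.asdict(cfg) | {"n_regions": len(regions), "mu_fraction": cfg.mu_fraction},
        ["regions.tsv", "regions.bed"],
    )
    return table


def cmd_cas3(
    ann: GenomeAnnotation,
    ess: EssentialityMap,
    protospacer_pos: int,
    outdir,
    n_colonies: int = 200,
    endpoint_model: str = "uniform",
    p: float | None = None,
    escaper_prob: float = 0.0,
    panel_spacing: int = 2000,
    max_amplicon: int = DEFAULT_MAX_AMPLICON,
    seed: int = 0,
    protect_unknown: bool = False,
    force: bool = False,
) -> dict:
    """Simulate a Cas3 deletion screen at one protospacer.

    Writes the permitted window, the simulated library (TSV + BED), the
    tiling band matrix, the deletion-length histogram, and the per-colony
    inferred bounds with their bracketing status.
    """
    outdir = _prepare_outdir(outdir, force)
    window = max_deletion_window(ann, ess, protospacer_pos, protect_unknown)
    events = simulate_deletion_library(
        window, protospacer_pos, n_colonies, endpoint_model, p, escaper_prob, seed
    )
    panel = make_tiling_panel(window[0], window[1], spacing=panel_spacing)
    bands = band_matrix(events, panel, max_amplicon)
    hist = deletion_length_histogram(events, bin_width=1000)

    lib = pd.DataFrame(
        {
            "colony": [f"c{i + 1}" for i in range(len(events))],
            "left_end": [e.left_end for e in events],
            "right_end": [e.right_end for e in events],
            "length": [e.length for e in events],
        }
    )
    lib.to_csv(outdir / "library.tsv", sep="\t", index=False)
    with open(outdir / "library.bed", "w") as fh:
        for i, e in enumerate(events):
            if e.length > 0:
                fh.write(f"{ann.sequence_id}\t{e.left_end}\t{e.right_end}\tc{i + 1}\t{e.length}\t.\n")
    bands.to_csv(outdir / "bands.tsv", sep="\t", index=False)
    hist.to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)

    inferred = []
    n_bracketed = 0
    for i, e in enumerate(events):
        bounds = infer_deletion_bounds(list(bands.iloc[i]), panel, max_amplicon, ann.length)
        if bounds.outer is None:
            bracketed = True  # no primer destroyed -> no boundary claim made
        else:
            bracketed = bounds.outer[0] <= e.left_end and e.right_end <= bounds.outer[1]
            if bounds.inner is not None:
                bracketed = bracketed and e.left_end <= bounds.inner[0] and bounds.inner[1] <= e.right_end
        n_bracketed += bracketed
        inferred.append(
            {
                "colony": f"c{i + 1}",
                "outer_left": bounds.outer[0] if bounds.outer else "",
                "outer_right": bounds.outer[1] if bounds.outer else "",
                "inner_left": bounds.inner[0] if bounds.inner else "",
                "inner_right": bounds.inner[1] if bounds.inner else "",
                "contradictory": bounds.contradictory,
                "true_left": e.left_end,
                "true_right": e.right_end,
                "bracketed": bracketed,
            }
        )
    pd.DataFrame(inferred).to_csv(outdir / "inference.tsv", sep="\t", index=False)

    report = {
        "window": list(window),
        "protospacer_pos": protospacer_pos,
        "n_colonies": n_colonies,
        "n_bracketed": int(n_bracketed),
        "n_escapers": int(sum(e.length == 0 for e in events)),
        "mean_length": float(lib["length"].mean()),
    }
    (outdir / "window.json").write_text(json.dumps(report, indent=1) + "\n")
    _write_manifest(
        outdir,
        "cas3",
        {
            "protospacer_pos": protospacer_pos,
            "endpoint_model": endpoint_model,
            "p": p,
            "escaper_prob": escaper_prob,
            "panel_spacing": panel_spacing,
            "max_amplicon": max_amplicon,
            "seed": seed,
            "n_colonies": n_colonies,
        },
        ["library.tsv", "library.bed", "bands.tsv", "length_histogram.tsv", "inference.tsv", "window.json"],
    )
    return report
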