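"""Readers and writers for every on-disk format the pipeline touches.

Standard formats (GenBank, GFF3, FASTA) go through Biopython/gffutils;
the SBML Level-3+FBC subset is read through cobrapy (read-only).  The
canonical model fixture format is a small documented JSON dialect::

    {
      "id": "toy",
      "metabolites": [{"id": "C", "compartment": "c"}, ...],
      "reactions": [
        {"id": "R_up", "stoichiometry": {"C": 1.0},
         "lower_bound": 0.0, "upper_bound": 10.0, "gpr": ""},
        ...
      ],
      "objective": "R_bio"
    }

Internal coordinates are 0-based half-open everywhere; GenBank's 1-based
inclusive convention and GFF3's 1-based inclusive columns are converted
exactly at these boundaries and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotation import GeneFeature, GenomeAnnotation
from .errors import ParseError, ValidationError
from .homology import EssentialityMap
from .models import ModelDocument, Reaction

if TYPE_CHECKING:  # pragma: no cover
    from .regions import DispensableRegion


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotation(path, format: str = "genbank", fasta=None) -> GenomeAnnotation:
    """Read a genome annotation.

    ``format='genbank'`` reads a flat file (1-based inclusive locations
    become 0-based half-open).  ``format='gff3'`` additionally requires
    ``fasta``, the genome nucleotide FASTA, from which CDS proteins are
    extracted by translation with NCBI table 11.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path)
    if format == "gff3":
        if fasta is None:
            raise ValidationError("GFF3 input requires a companion genome FASTA")
        return _read_gff3(path, Path(fasta))
    raise ValidationError(f"unknown annotation format {format!r}")


def _read_genbank(path: Path) -> GenomeAnnotation:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no GenBank records found")
    rec = records[0]
    features = []
    for fe in rec.features:
        if fe.type != "CDS":
            continue
        quals = fe.qualifiers
        locus = quals.get("locus_tag", [None])[0]
        if locus is None:
            raise ParseError(f"{path}: CDS at {fe.location} lacks a locus_tag")
        protein = quals.get("translation", [None])[0]
        features.append(
            GeneFeature(
                locus_tag=locus,
                start=int(fe.location.start),
                end=int(fe.location.end),
                strand="+" if fe.location.strand >= 0 else "-",
                product=quals.get("product", [""])[0],
                protein=protein,
            )
        )
    seq = str(rec.seq).upper() if len(rec.seq) else None
    return GenomeAnnotation(rec.id, len(rec.seq), features, sequence=seq)


def _read_gff3(path: Path, fasta: Path) -> GenomeAnnotation:
    import gffutils

    genome = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
    if not genome:
        raise ParseError(f"{fasta}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
        )
    except Exception as exc:  # gffutils raises assorted types
        raise ParseError(f"{path}: malformed GFF3: {exc}") from exc
    features = []
    seqid = None
    for f in db.features_of_type("CDS", order_by="start"):
        seqid = f.seqid
        if f.seqid not in genome:
            raise ParseError(f"{path}: sequence {f.seqid!r} absent from FASTA")
        locus = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [None])[0]
        if locus is None:
            raise ParseError(f"{path}: CDS line {f.start}..{f.end} lacks locus_tag/ID")
        start, end = f.start - 1, f.end  # GFF3 is 1-based inclusive
        cds = genome[f.seqid][start:end]
        if f.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        protein = str(Seq(cds).translate(table=11)).rstrip("*")
        features.append(
            GeneFeature(
                locus_tag=locus,
                start=start,
                end=end,
                strand="-" if f.strand == "-" else "+",
                product=(f.attributes.get("product") or [""])[0],
                protein=protein,
            )
        )
    if seqid is None:
        seqid = next(iter(genome))
    return GenomeAnnotation(seqid, len(genome[seqid]), features, sequence=genome[seqid])


def write_annotation(ann: GenomeAnnotation, path, format: str = "genbank", fasta=None) -> None:
    """Write an annotation re-readable by :func:`read_annotation`.

    For GFF3, ``fasta`` names the companion genome FASTA to write
    (required when the annotation carries a sequence).
    """
    path = Path(path)
    if format == "genbank":
        _write_genbank(ann, path)
    elif format == "gff3":
        _write_gff3(ann, path, fasta)
    else:
        raise ValidationError(f"unknown annotation format {format!r}")


def _write_genbank(ann: GenomeAnnotation, path: Path) -> None:
    seq = ann.sequence if ann.sequence is not None else "N" * ann.length
    rec = SeqRecord(
        Seq(seq),
        id=ann.sequence_id,
        name=ann.sequence_id[:16],
        description="synthetic annotation",
        annotations={"molecule_type": "DNA"},
    )
    for f in ann.features:
        qualifiers = {"locus_tag": [f.locus_tag], "product": [f.product]}
        if f.protein is not None:
            qualifiers["translation"] = [f.protein]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def _write_gff3(ann: GenomeAnnotation, path: Path, fasta) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.sequence_id} 1 {ann.length}\n")
        for f in ann.features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag};product={f.product}"
            fh.write(
                f"{ann.sequence_id}\tgenoslim\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )
    if fasta is not None:
        if ann.sequence is None:
            raise ValidationError("annotation has no sequence to write as FASTA")
        with open(fasta, "w") as fh:
            fh.write(f">{ann.sequence_id}\n")
            for i in range(0, ann.length, 70):
                fh.write(ann.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Metabolic models
# ---------------------------------------------------------------------------


def read_model(path, format: str | None = None) -> ModelDocument:
    """Read a model (JSON dialect, or SBML Level-3+FBC subset read-only)."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return _read_model_json(path)
    if format == "sbml":
        return _read_model_sbml(path)
    raise ValidationError(f"unknown model format {format!r}")


def _read_model_json(path: Path) -> ModelDocument:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    try:
        mets = {m["id"]: m.get("compartment", "c") for m in doc["metabolites"]}
        reactions = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                float(r["lower_bound"]),
                float(r["upper_bound"]),
                r.get("gpr", ""),
            )
            for r in doc["reactions"]
        ]
        return ModelDocument(doc.get("id", path.stem), mets, reactions, doc["objective"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing required model key {exc}") from exc


def _read_model_sbml(path: Path) -> ModelDocument:
    from cobra.io import read_sbml_model
    from cobra.util.solver import linear_reaction_coefficients

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: SBML read failed: {exc}") from exc
    objective = next(iter(linear_reaction_coefficients(cm)), None)
    if objective is None:
        raise ParseError(f"{path}: SBML model has no linear objective")
    mets = {m.id: (m.compartment or "c") for m in cm.metabolites}
    reactions = [
        Reaction(
            r.id,
            {m.id: coeff for m, coeff in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
            r.gene_reaction_rule,
        )
        for r in cm.reactions
    ]
    return ModelDocument(cm.id or path.stem, mets, reactions, objective.id)


def write_model(model: ModelDocument, path) -> None:
    """Write the JSON model dialect (SBML writing is out of scope)."""
    doc = {
        "id": model.id,
        "metabolites": [{"id": m, "compartment": c} for m, c in model.metabolites.items()],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr,
            }
            for r in model.reactions
        ],
        "objective": model.objective_id,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Regions / BED
# ---------------------------------------------------------------------------


def write_regions_bed(regions: list["DispensableRegion"], path, sequence_id: str = "chr") -> None:
    """BED6 lines (0-based half-open) sorted by start; name = ``rank_k``."""
    ordered = sorted(regions, key=lambda r: r.start_coord)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_coord < a.end_coord:
            raise ValidationError(
                f"regions rank_{a.rank} and rank_{b.rank} overlap; BED export requires disjoint regions"
            )
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(
                f"{sequence_id}\t{r.start_coord}\t{r.end_coord}\trank_{r.rank}\t"
                f"{r.length_span}\t.\n"
            )


def read_regions_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED back as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: BED line has <4 columns: {line!r}")
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return out


# ---------------------------------------------------------------------------
# Essentiality maps, locus lists, proteomes, config
# ---------------------------------------------------------------------------


def write_essentiality(ess: EssentialityMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_tag\tlabel\tprovenance\n")
        for locus, label in ess.labels.items():
            prov = ess.provenance.get(locus) or ""
            fh.write(f"{locus}\t{label}\t{prov}\n")


def read_essentiality(path) -> EssentialityMap:
    labels: dict[str, str] = {}
    prov: dict[str, str | None] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus_tag"):
            raise ParseError(f"{path}: expected header starting with 'locus_tag'")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            labels[parts[0]] = parts[1]
            prov[parts[0]] = parts[2] if len(parts) > 2 and parts[2] else None
    return EssentialityMap(labels, prov)


def read_locus_list(path) -> set[str]:
    """Plain-text/TSV list of locus or gene ids (first column, # comments)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.add(line.split("\t")[0])
    return out


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def load_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid config: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return doc
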