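"""Readers and writers for every external representation.

Gene tables are GFF3 (1-based inclusive, converted to internal 0-based
half-open on read). Domain hits, taxonomy and family membership are headered
TSV; domain-hit coordinates follow the common scanner convention of 1-based
inclusive amino-acid positions and are likewise converted. All writers are
the exact inverses of the readers on valid files.
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import networkx as nx
import pandas as pd
from gffutils.feature import feature_from_line

from .records import DomainHit, FamilyMembership, GeneRecord, TaxonRecord, Taxonomy

log = logging.getLogger(__name__)

#: Attribute keys probed, in order, for the protein accession of a CDS.
ACCESSION_ATTRIBUTES = ("protein_id", "ID", "Name")


class FormatError(ValueError):
    """Raised for unrecoverable problems in an input file."""


# ---------------------------------------------------------------------------
# GFF3 gene tables
# ---------------------------------------------------------------------------

def read_gff(path: str | Path, feature_types: tuple[str, ...] = ("CDS",)) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    One :class:`GeneRecord` per retained feature. 1-based inclusive GFF
    coordinates become 0-based half-open. ``gene_ordinal`` is assigned by
    ascending start coordinate within each replicon; unsorted input is
    sorted, not rejected. A missing strand or accession attribute is a
    record-level error reported with its line number.
    """
    path = Path(path)
    genome_id = path.stem
    raw: list[tuple[str, int, int, int, str]] = []
    errors: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed line
                errors.append(f"line {lineno}: unparseable ({exc})")
                continue
            if feat.featuretype not in feature_types:
                continue
            if feat.strand not in ("+", "-"):
                errors.append(f"line {lineno}: missing strand")
                continue
            accession = None
            for key in ACCESSION_ATTRIBUTES:
                if key in feat.attributes:
                    accession = feat.attributes[key][0]
                    break
            if accession is None:
                errors.append(f"line {lineno}: no accession attribute "
                              f"(tried {', '.join(ACCESSION_ATTRIBUTES)})")
                continue
            raw.append((feat.seqid, feat.start - 1, feat.end,
                        1 if feat.strand == "+" else -1, accession))
    if errors:
        raise FormatError(f"{path}: {len(errors)} bad records: " + "; ".join(errors[:10]))

    records: list[GeneRecord] = []
    by_replicon: dict[str, list[tuple[int, int, int, str]]] = {}
    for seqid, start, end, strand, acc in raw:
        by_replicon.setdefault(seqid, []).append((start, end, strand, acc))
    for seqid in sorted(by_replicon):
        rows = sorted(by_replicon[seqid])
        for ordinal, (start, end, strand, acc) in enumerate(rows):
            records.append(GeneRecord(genome_id, seqid, ordinal, start, end, strand, acc))
    return records


def write_gff(genes: list[GeneRecord], path: str | Path) -> None:
    """Write gene records as GFF3 CDS features (inverse of :func:`read_gff`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.start)):
            strand = "+" if g.strand == 1 else "-"
            fh.write(f"{g.replicon_id}\tgenecontext\tCDS\t{g.start + 1}\t{g.end}\t."
                     f"\t{strand}\t0\tID={g.protein_accession};protein_id={g.protein_accession}\n")


# ---------------------------------------------------------------------------
# TSV tables: domain hits, taxonomy, family membership
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a domain/feature hit table.

    Columns: protein, label, start, end, score (score optional/blank).
    Coordinates are 1-based inclusive in the file. Malformed rows are
    rejected and reported with a count rather than aborting the read.
    """
    df = _read_table(path, ("protein", "label", "start", "end"))
    hits: list[DomainHit] = []
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            start = int(row.start) - 1
            end = int(row.end)
            score = None
            if "score" in df.columns and row.score != "":
                score = float(row.score)
            hits.append(DomainHit(row.protein, row.label, start, end, score))
        except (ValueError, TypeError):
            rejected += 1
    if rejected:
        log.warning("%s: rejected %d malformed hit rows", path, rejected)
    return hits


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    rows = [{"protein": h.protein_accession, "label": h.label,
             "start": h.start + 1, "end": h.end,
             "score": "" if h.score is None else f"{h.score:g}"} for h in hits]
    pd.DataFrame(rows, columns=["protein", "label", "start", "end", "score"]).to_csv(
        path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = _read_table(path, ("genome", "species", "phylum", "superkingdom"))
    return Taxonomy([TaxonRecord(r.genome, r.species, r.phylum, r.superkingdom)
                     for r in df.itertuples(index=False)])


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    rows = [{"genome": t.genome_id, "species": t.species, "phylum": t.phylum,
             "superkingdom": t.superkingdom} for t in taxonomy.records]
    pd.DataFrame(rows, columns=["genome", "species", "phylum", "superkingdom"]).to_csv(
        path, sep="\t", index=False)


def read_family(path: str | Path) -> list[FamilyMembership]:
    df = _read_table(path, ("protein", "family"))
    members = []
    rejected = 0
    for r in df.itertuples(index=False):
        if not r.protein or not r.family:
            rejected += 1
            continue
        members.append(FamilyMembership(r.protein, r.family))
    if rejected:
        log.warning("%s: rejected %d empty family rows", path, rejected)
    return members


def write_family(members: list[FamilyMembership], path: str | Path) -> None:
    rows = [{"protein": m.protein_accession, "family": m.query_family} for m in members]
    pd.DataFrame(rows, columns=["protein", "family"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------

def write_graph(graph: nx.Graph, basepath: str | Path) -> list[str]:
    """Write a graph as both edge-list TSV and GML; return the filenames."""
    basepath = Path(basepath)
    edge_path = basepath.with_suffix(".edges.tsv")
    gml_path = basepath.with_suffix(".gml")
    rows = [{"source": u, "target": v, **{k: d[k] for k in sorted(d)}}
            for u, v, d in sorted(graph.edges(data=True))]
    cols = ["source", "target"] + sorted({k for r in rows for k in r} - {"source", "target"})
    pd.DataFrame(rows, columns=cols).to_csv(edge_path, sep="\t", index=False)
    nx.write_gml(graph, gml_path)
    return [edge_path.name, gml_path.name]


def write_results(tables: dict[str, pd.DataFrame], graphs: dict[str, nx.Graph],
                  outdir: str | Path, parameters: dict | None = None,
                  seed: int | None = None) -> dict:
    """Write all pipeline result tables/graphs plus a JSON manifest.

    Tables land as ``<name>.tsv``; each graph as ``<name>.edges.tsv`` and
    ``<name>.gml``. The manifest lists every file, the resolved parameters
    and the seed, so a run is fully reconstructible from its output
    directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, list[str] | str] = {}
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(outdir / fname, sep="\t", index=False)
        files[name] = fname
    for name, graph in graphs.items():
        files[name] = write_graph(graph, outdir / name)
    manifest = {
        "files": files,
        "parameters": _jsonable(parameters or {}),
        "seed": seed,
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return str(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
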