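"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is 0-based half-open and maps directly onto the internal
representation; GFF3 is 1-based closed and is converted on read
(``start - 1``) and back on write.  All writers round-trip through the
corresponding readers losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel
from .intervals import GenomicInterval, PeakSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_count_matrix",
    "write_count_matrix",
    "read_json",
    "write_json",
]


def read_bed(path: str | Path, label: str = "") -> PeakSet:
    """Read BED3/BED6 into a PeakSet (column 4, if present, is the id)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            intervals.append(GenomicInterval(fields[0], start, end, name))
    return PeakSet(intervals, label=label or Path(path).stem)


def write_bed(peaks: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed, converted internally).

    ``gene`` features define the model; ``exon`` features attach to their
    gene via the ``Parent`` (or ``ID`` prefix) attribute.  A gene with no
    exon lines becomes a single-exon model over its span.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            scaffold, _, ftype, start, end, _, strand, _, attrs = f
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = GenomicInterval(scaffold, int(start) - 1, int(end))
            if ftype == "gene":
                gid = attrd.get("ID", f"gene_{lineno}")
                genes[gid] = {"scaffold": scaffold, "strand": strand, "span": iv}
            elif ftype == "exon":
                parent = attrd.get("Parent") or attrd.get("ID", "").rsplit(".", 1)[0]
                exons.setdefault(parent, []).append(iv)
    out = []
    for gid, g in genes.items():
        ex = tuple(exons.get(gid)) if gid in exons else (g["span"],)
        out.append(GeneModel(gid, g["scaffold"], g["strand"], ex))
    return sorted(out, key=lambda g: (g.scaffold, g.start))


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tpeakdiff\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tpeakdiff\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "size"])
    return dict(zip(df["scaffold"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Counts TSV: peak ids in the first column, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="peak_id")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
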