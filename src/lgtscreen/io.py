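"""Readers and writers for the flat-text formats the screen touches.

FASTA goes through Biopython.  BED, bedGraph and the pair-placement TSV are
simple tab dialects with strict coordinate conventions (0-based half-open),
parsed here so errors carry line numbers.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import PAIR_COLUMNS, ScaffoldSet, TruthSet
from .errors import ParseError


def read_fasta(path: str | os.PathLike) -> ScaffoldSet:
    """Read a FASTA file into a :class:`ScaffoldSet`.

    A description of the form ``taxon=NAME`` after the identifier is picked
    up as the sequence's taxon label.
    """
    out = ScaffoldSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = None
        for tok in rec.description.split()[1:]:
            if tok.startswith("taxon="):
                taxon = tok[len("taxon="):]
        out.add(rec.id, str(rec.seq), taxon=taxon)
    return out


def write_fasta(scaffolds: ScaffoldSet, path: str | os.PathLike,
                width: int = 80) -> None:
    records = []
    for name, seq in scaffolds:
        desc = f"taxon={scaffolds.taxa[name]}" if name in scaffolds.taxa else ""
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_truth(truth: TruthSet, implants_bed: str | os.PathLike,
                contaminants_tsv: str | os.PathLike) -> None:
    """Write ground truth: implants as BED (0-based half-open), contaminants as TSV."""
    with open(implants_bed, "w") as fh:
        for t in truth.implants:
            fh.write(f"{t.scaffold}\t{t.start}\t{t.end}\t{t.taxon}\t"
                     f"{t.divergence:.4f}\n")
    with open(contaminants_tsv, "w") as fh:
        fh.write("scaffold\ttaxon\n")
        for c in truth.contaminants:
            fh.write(f"{c.scaffold}\t{c.taxon}\n")


def read_truth(implants_bed: str | os.PathLike,
               contaminants_tsv: str | os.PathLike | None = None) -> TruthSet:
    from .containers import ContaminantTruth, ImplantTruth
    truth = TruthSet()
    with open(implants_bed) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{implants_bed}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{implants_bed}:{lineno}: non-integer coordinate") from None
            taxon = parts[3] if len(parts) > 3 else ""
            div = float(parts[4]) if len(parts) > 4 else 0.0
            truth.implants.append(
                ImplantTruth(parts[0], start, end, taxon, div))
    if contaminants_tsv is not None:
        df = pd.read_csv(contaminants_tsv, sep="\t")
        for row in df.itertuples(index=False):
            truth.contaminants.append(ContaminantTruth(str(row.scaffold),
                                                       str(row.taxon)))
    return truth


def write_pairs(pairs: pd.DataFrame, path: str | os.PathLike) -> None:
    pairs.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def read_pairs(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "scaffold": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing pair columns {missing}")
    return df


def write_bedgraph(track: dict[str, list[tuple[int, int, float]]],
                   path: str | os.PathLike) -> None:
    """Write per-scaffold (start, end, value) runs; zero runs are omitted."""
    with open(path, "w") as fh:
        for scaffold in sorted(track):
            for start, end, value in sorted(track[scaffold]):
                if value != 0:
                    fh.write(f"{scaffold}\t{start}\t{end}\t{value:g}\n")


def read_bedgraph(path: str | os.PathLike) -> dict[str, list[tuple[int, int, float]]]:
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                rec = (int(parts[1]), int(parts[2]), float(parts[3]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from None
            track.setdefault(parts[0], []).append(rec)
    for runs in track.values():
        runs.sort()
    return track


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (scaffold, start, end[, name[, score[, strand]]]) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
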