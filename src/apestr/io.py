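"""Readers and writers for the pipeline's file formats.

All tabular outputs are TSV/CSV with a leading ``#`` provenance comment line
(tool version, subcommand, seed); readers skip comment lines.  Coordinates
are 0-based half-open throughout.  FASTQ is phred-33, parsed with
Biopython's FastqGeneralIterator.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from . import __version__
from .allele_caller import CallStatus, GenotypeCall, LocusDefinition
from .str_model import Motif

__all__ = [
    "provenance_line",
    "read_fastq",
    "write_fastq",
    "read_locus_table",
    "write_locus_table",
    "read_group_table",
    "write_group_table",
    "write_genotype_calls",
    "read_genotype_calls",
    "write_json",
]


def provenance_line(command: str, seed: int | None = None, **params) -> str:
    bits = [f"apestr v{__version__}", f"command={command}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits.extend(f"{k}={v}" for k, v in sorted(params.items()))
    return "# " + " ".join(bits)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str) -> list[tuple[str, str, str]]:
    """Read phred-33 FASTQ into (id, sequence, quality) triples.

    Malformed records are rejected with the index of the failing record.
    """
    out: list[tuple[str, str, str]] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return out
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record index {len(out)}: {exc}"
                ) from exc
            out.append((title.split()[0], seq.upper(), qual))


def write_fastq(
    path: str, reads: Iterable[tuple[str, str]], quality: int = 30
) -> None:
    """Write (id, sequence) pairs with a constant phred quality."""
    records = (
        SeqRecord(
            Seq(seq),
            id=rid,
            description="",
            letter_annotations={"phred_quality": [quality] * len(seq)},
        )
        for rid, seq in reads
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# locus and group tables

_LOCUS_COLUMNS = ["name", "anchor5", "flank3", "motifs", "canonical", "min_bp", "max_bp"]


def write_locus_table(path: str, loci: Sequence[LocusDefinition], provenance: str = "") -> None:
    rows = [
        {
            "name": l.name,
            "anchor5": l.anchor5,
            "flank3": l.flank3,
            "motifs": ",".join(m.sequence for m in l.motifs),
            "canonical": l.canonical.sequence,
            "min_bp": l.region_range[0],
            "max_bp": l.region_range[1],
        }
        for l in loci
    ]
    _write_table(path, pd.DataFrame(rows, columns=_LOCUS_COLUMNS), provenance, sep="\t")


def read_locus_table(path: str) -> list[LocusDefinition]:
    df = _read_table(path, sep="\t")
    missing = [c for c in _LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing locus-table columns {missing}")
    loci = []
    for i, row in df.iterrows():
        try:
            motifs = tuple(Motif(m) for m in str(row["motifs"]).split(","))
            loci.append(
                LocusDefinition(
                    name=str(row["name"]),
                    anchor5=str(row["anchor5"]),
                    flank3=str(row["flank3"]),
                    motifs=motifs,
                    canonical=Motif(str(row["canonical"])),
                    region_range=(int(row["min_bp"]), int(row["max_bp"])),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return loci


def write_group_table(path: str, group_of: Mapping[str, str], provenance: str = "") -> None:
    df = pd.DataFrame(
        sorted(group_of.items()), columns=["sample", "group"]
    )
    _write_table(path, df, provenance, sep="\t")


def read_group_table(path: str) -> dict[str, str]:
    df = _read_table(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: group table needs 'sample' and 'group' columns")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# genotype calls

_CALL_COLUMNS = [
    "sample", "locus", "allele1_seq", "allele2_seq", "array1", "array2",
    "ce1", "ce2", "depth1", "depth2", "status",
]


def write_genotype_calls(
    path: str, calls: Iterable[GenotypeCall], provenance: str = ""
) -> None:
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample, c.locus)):
        a = list(c.alleles)
        d = list(c.depths)
        if c.status is CallStatus.GENOTYPED_HOM and len(a) == 1:
            a = [a[0], a[0]]
            d = [d[0], None]
        while len(a) < 2:
            a.append(None)
        while len(d) < 2:
            d.append(None)
        rows.append(
            {
                "sample": c.sample,
                "locus": c.locus,
                "allele1_seq": a[0].full_seq if a[0] else "",
                "allele2_seq": a[1].full_seq if a[1] else "",
                "array1": a[0].array_seq if a[0] else "",
                "array2": a[1].array_seq if a[1] else "",
                "ce1": a[0].ce_label if a[0] else "",
                "ce2": a[1].ce_label if a[1] else "",
                "depth1": d[0],
                "depth2": d[1],
                "status": c.status.value,
            }
        )
    _write_table(path, pd.DataFrame(rows, columns=_CALL_COLUMNS), provenance, sep=",")


def read_genotype_calls(path: str) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    missing = [c for c in _CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing genotype columns {missing}")
    for col in ("allele1_seq", "allele2_seq", "array1", "array2", "ce1", "ce2"):
        df[col] = df[col].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# generic helpers


def _write_table(path: str, df: pd.DataFrame, provenance: str, sep: str) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance.rstrip("\n") + "\n")
        df.to_csv(fh, sep=sep, index=False)


def _read_table(path: str, sep: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse table: {exc}") from exc


def write_json(path: str, payload: dict, provenance: str = "") -> None:
    out = dict(payload)
    if provenance:
        out["_provenance"] = provenance.lstrip("# ")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
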