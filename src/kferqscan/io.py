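"""FASTA ingestion (UniProt header dialect) and the finder report writer."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import logging

from Bio import SeqIO

from kferqscan.motif_engine import AMINO_ACIDS, MotifMatch

logger = logging.getLogger(__name__)

__all__ = ["ProteinRecord", "read_fasta", "write_fasta", "write_finder_report"]

# sp|P12345|TEST_HUMAN Protein name OS=Homo sapiens OX=9606 GN=TST PE=1 SV=2
_UNIPROT_HEADER = re.compile(
    r"^(?P<db>sp|tr)\|(?P<acc>[^|]+)\|(?P<entry>\S+)\s*(?P<rest>.*)$"
)
_GN = re.compile(r"\bGN=(\S+)")
_OS = re.compile(r"\bOS=(.+?)(?=\s+\w\w=|$)")

_STATUS = {"sp": "Swiss-Prot", "tr": "TrEMBL"}


@dataclass
class ProteinRecord:
    """One proteome entry: identity, review status and sequence."""

    accession: str
    entry_name: str
    status: str  # Swiss-Prot | TrEMBL | unknown
    protein_names: str
    gene_name: str
    organism: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def _parse_header(description: str) -> dict:
    m = _UNIPROT_HEADER.match(description)
    if m:
        rest = m.group("rest")
        gn = _GN.search(rest)
        os_ = _OS.search(rest)
        # protein names = free text before the first KEY= token
        name = re.split(r"\s+\w\w=", rest)[0].strip()
        return {
            "accession": m.group("acc"),
            "entry_name": m.group("entry"),
            "status": _STATUS.get(m.group("db"), "unknown"),
            "protein_names": name,
            "gene_name": gn.group(1) if gn else "",
            "organism": os_.group(1).strip() if os_ else "",
        }
    first = description.split()[0] if description.split() else description
    rest = description[len(first):].strip()
    return {
        "accession": first,
        "entry_name": first,
        "status": "unknown",
        "protein_names": rest,
        "gene_name": "",
        "organism": "",
    }


def read_fasta(path, reviewed_only: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    UniProt-style headers (``sp|ACC|ENTRY ... OS=... GN=...``) are parsed
    into accession, entry name, review status, protein/gene names; plain
    headers fall back to the first token as identifier with unknown status.
    Lowercase sequence letters are uppercased with a warning.  Duplicate
    accessions or an empty file raise :class:`ValueError`.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(seq_rec.description)
        seq = str(seq_rec.seq)
        if seq != seq.upper():
            logger.warning("protein %s: lowercase residues uppercased", fields["accession"])
            seq = seq.upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            logger.warning(
                "protein %s: non-standard residues %s will never match a motif",
                fields["accession"], "".join(sorted(bad)),
            )
        records.append(ProteinRecord(sequence=seq, **fields))
        seen[fields["accession"]] = seen.get(fields["accession"], 0) + 1
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    dups = sorted(acc for acc, n in seen.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate accessions in {path}: {', '.join(dups)}")
    if reviewed_only:
        records = [r for r in records if r.status == "Swiss-Prot"]
        if not records:
            raise ValueError(f"no reviewed (Swiss-Prot) records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records back out; headers reproduce the UniProt dialect when
    the review status is known."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.status in ("Swiss-Prot", "TrEMBL"):
                db = "sp" if rec.status == "Swiss-Prot" else "tr"
                header = f"{db}|{rec.accession}|{rec.entry_name}"
                if rec.protein_names:
                    header += f" {rec.protein_names}"
                if rec.organism:
                    header += f" OS={rec.organism}"
                if rec.gene_name:
                    header += f" GN={rec.gene_name}"
            else:
                header = rec.accession
                if rec.protein_names:
                    header += f" {rec.protein_names}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


FINDER_COLUMNS = (
    "entry_name",
    "status",
    "protein_names",
    "gene_name",
    "length",
    "motif_composition",
    "motif_position",
    "motif_type",
)


def write_finder_report(
    matches: Sequence[MotifMatch],
    records: Sequence[ProteinRecord],
    path,
) -> None:
    """Write the per-motif report: one TSV row per match.

    Columns: entry name, review status, protein names, gene name, protein
    length, motif composition (the pentapeptide), motif position (1-based
    start residue) and motif type.  Rows are ordered by accession, then
    start position, then class, so output is byte-identical across runs.
    """
    by_acc = {r.accession: r for r in records}
    missing = sorted({m.protein_id for m in matches} - set(by_acc))
    if missing:
        raise ValueError(f"matches reference unknown proteins: {', '.join(missing)}")

    order = {c: i for i, c in enumerate(
        ("canonical", "phospho_generated", "acetyl_generated",
         "n_canonical", "n_phospho", "n_acetyl"))}
    rows = sorted(matches, key=lambda m: (m.protein_id, m.start, order[m.motif_class.value]))
    with open(path, "w") as fh:
        fh.write("\t".join(FINDER_COLUMNS) + "\n")
        for m in rows:
            rec = by_acc[m.protein_id]
            fh.write(
                "\t".join(
                    [
                        rec.entry_name,
                        rec.status,
                        rec.protein_names,
                        rec.gene_name,
                        str(rec.length),
                        m.pentapeptide,
                        str(m.start),
                        m.motif_class.value,
                    ]
                )
                + "\n"
            )
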