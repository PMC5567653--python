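"""Sequence and label I/O for the DGK catalytic-domain pipeline.

Vertebrate diacylglycerol kinases comprise ten isozymes (alpha..kappa)
grouped into five classes by domain architecture:

    I: alpha, beta, gamma   II: delta, eta, kappa   III: epsilon
    IV: zeta, iota          V: theta

Sequences arrive as FASTA (unaligned) or aligned FASTA / Clustal, and
isozyme labels as a TSV group table.  Labels embedded in FASTA headers
(``id|accession|species|taxon_group|isozyme``) are a convenience; the
group table, when given, is authoritative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO

from .alignment import Alignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "XBZU"
RESIDUE_ALPHABET = set(AA20 + AMBIGUOUS)
GAP_CHARS = "-."

ISOZYMES = ("alpha", "beta", "gamma", "delta", "epsilon",
            "zeta", "eta", "theta", "iota", "kappa")

#: fixed isozyme -> class scheme shared by all vertebrate DGKs
ISOZYME_TO_CLASS = {
    "alpha": "I", "beta": "I", "gamma": "I",
    "delta": "II", "eta": "II", "kappa": "II",
    "epsilon": "III",
    "zeta": "IV", "iota": "IV",
    "theta": "V",
}

DGK_CLASSES = ("I", "II", "III", "IV", "V")

TAXON_GROUPS = ("mammal", "bird", "reptile", "amphibian", "fish", "other")

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "ί": "iota",
    "κ": "kappa",
}


class SeqIOError(ValueError):
    """Malformed sequence or label input."""


def normalize_isozyme(token: str) -> str:
    """Canonical Latin isozyme name from a Greek letter or Latin spelling."""
    tok = token.strip()
    if tok in _GREEK:
        return _GREEK[tok]
    low = tok.lower()
    if low in ISOZYMES or low == "unknown":
        return low
    raise SeqIOError(
        f"unknown isozyme token {token!r}; expected one of {ISOZYMES} "
        "(Greek letters accepted)")


def class_of_isozyme(isozyme: str) -> str:
    return ISOZYME_TO_CLASS.get(isozyme, "unknown")


@dataclass
class SequenceRecord:
    """One protein sequence with its identity and group labels."""

    id: str
    residues: str
    accession: str = ""
    species: str = ""
    taxon_group: str = "other"
    isozyme: str = "unknown"
    dgk_class: str = "unknown"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in RESIDUE_ALPHABET:
                raise SeqIOError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos}")
        if self.isozyme != "unknown":
            derived = class_of_isozyme(self.isozyme)
            if self.dgk_class == "unknown":
                self.dgk_class = derived
            elif self.dgk_class != derived:
                raise SeqIOError(
                    f"record {self.id!r}: isozyme {self.isozyme} belongs to "
                    f"class {derived}, not {self.dgk_class}")

    def __len__(self) -> int:
        return len(self.residues)


def _parse_header(description: str) -> dict:
    """Parse ``id|accession|species|group|isozyme``; unparseable labels
    degrade to unknown rather than erroring (headers vary in the wild;
    the group table is the authoritative label source)."""
    fields = [f.strip() for f in description.split("|")]
    info = {"id": fields[0]}
    if len(fields) > 1:
        info["accession"] = fields[1]
    if len(fields) > 2:
        info["species"] = fields[2]
    if len(fields) > 3 and fields[3].lower() in TAXON_GROUPS:
        info["taxon_group"] = fields[3].lower()
    if len(fields) > 4:
        try:
            info["isozyme"] = normalize_isozyme(fields[4])
        except SeqIOError:
            pass
    return info


def read_fasta(path) -> list[SequenceRecord]:
    """Read unaligned protein FASTA.  Gap characters are rejected here;
    use :func:`read_alignment` for aligned input."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        info = _parse_header(rec.description)
        if info["id"] in seen:
            raise SeqIOError(f"duplicate sequence id {info['id']!r}")
        seen.add(info["id"])
        seq = str(rec.seq).upper().rstrip("*")
        for pos, ch in enumerate(seq, start=1):
            if ch in GAP_CHARS:
                raise SeqIOError(
                    f"record {info['id']!r}: gap character at position {pos}; "
                    "unaligned FASTA may not contain gaps")
        records.append(SequenceRecord(residues=seq, **info))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as FASTA, 60-column wrapped, byte-stable."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            labeled = (rec.accession or rec.species
                       or rec.taxon_group != "other" or rec.isozyme != "unknown")
            if labeled:
                header = "|".join([rec.id, rec.accession, rec.species,
                                   rec.taxon_group, rec.isozyme])
            else:
                header = rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path, dialect: str = "aligned-fasta") -> Alignment:
    """Read a protein multiple alignment (aligned FASTA or Clustal).

    ``.`` gaps are normalised to ``-`` and residues upper-cased.  Ragged
    rows raise, naming the offending sequence.
    """
    if dialect == "aligned-fasta":
        entries = [(r.description.split("|")[0].strip(), str(r.seq))
                   for r in SeqIO.parse(str(path), "fasta")]
    elif dialect == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        entries = [(r.id, str(r.seq)) for r in aln]
    else:
        raise SeqIOError(f"unknown alignment dialect {dialect!r}")
    if not entries:
        raise SeqIOError(f"no alignment rows in {path}")
    ids, rows = [], []
    width = len(entries[0][1])
    for rid, row in entries:
        row = row.upper().replace(".", "-")
        if len(row) != width:
            raise SeqIOError(
                f"ragged alignment: row {rid!r} has length {len(row)}, "
                f"expected {width} (from row {entries[0][0]!r})")
        ids.append(rid)
        rows.append(row)
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


@dataclass
class GroupScheme:
    """Maps sequence ids to isozymes/classes plus optional named groups."""

    isozyme_of: dict = field(default_factory=dict)
    taxon_group_of: dict = field(default_factory=dict)
    species_of: dict = field(default_factory=dict)
    custom_groups: dict = field(default_factory=dict)

    def isozyme(self, seq_id: str) -> str:
        if seq_id not in self.isozyme_of:
            raise SeqIOError(f"sequence id {seq_id!r} not in group table")
        return self.isozyme_of[seq_id]

    def dgk_class(self, seq_id: str) -> str:
        return class_of_isozyme(self.isozyme(seq_id))

    def groups(self, grouping: str, ids) -> dict:
        """Partition ``ids`` into labelled groups.  Rows whose label is
        unknown under the grouping are silently left out (callers warn)."""
        out: dict[str, list] = {}
        if grouping == "by_class":
            for i in ids:
                lab = class_of_isozyme(self.isozyme_of.get(i, "unknown"))
                if lab != "unknown":
                    out.setdefault(lab, []).append(i)
        elif grouping == "by_isozyme":
            for i in ids:
                lab = self.isozyme_of.get(i, "unknown")
                if lab != "unknown":
                    out.setdefault(lab, []).append(i)
        elif grouping == "custom":
            if not self.custom_groups:
                raise SeqIOError("custom grouping requested but no named groups defined")
            idset = set(ids)
            for lab, members in self.custom_groups.items():
                hit = [i for i in ids if i in members]
                if hit:
                    out[lab] = hit
        else:
            raise SeqIOError(f"unknown grouping {grouping!r}")
        return out


def parse_group_table(path) -> GroupScheme:
    """Read the TSV group table (columns id, accession, species,
    taxon_group, isozyme)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "isozyme"}
    if not required.issubset(df.columns):
        raise SeqIOError(
            f"group table needs columns {sorted(required)}, got {list(df.columns)}")
    scheme = GroupScheme()
    for _, row in df.iterrows():
        sid = row["id"].strip()
        if sid in scheme.isozyme_of:
            raise SeqIOError(f"duplicate id {sid!r} in group table")
        scheme.isozyme_of[sid] = normalize_isozyme(row["isozyme"] or "unknown")
        if "taxon_group" in df.columns and row["taxon_group"]:
            tg = row["taxon_group"].strip().lower()
            if tg not in TAXON_GROUPS:
                raise SeqIOError(f"unknown taxon group {tg!r} for id {sid!r}")
            scheme.taxon_group_of[sid] = tg
        if "species" in df.columns:
            scheme.species_of[sid] = row["species"]
    return scheme


def write_group_table(scheme: GroupScheme, path) -> None:
    ids = sorted(scheme.isozyme_of)
    df = pd.DataFrame({
        "id": ids,
        "accession": ["" for _ in ids],
        "species": [scheme.species_of.get(i, "") for i in ids],
        "taxon_group": [scheme.taxon_group_of.get(i, "") for i in ids],
        "isozyme": [scheme.isozyme_of[i] for i in ids],
    })
    df.to_csv(path, sep="\t", index=False)
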