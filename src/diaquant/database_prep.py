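"""Protein sequence-database harmonization.

Protein summarization tools differ in how they infer proteins from shared
peptides, which confounds any benchmark of the summarization step itself.
The remedy implemented here is to harmonize the database up front: digest
every protein in silico with trypsin, remove every protein that shares a
tryptic peptide longer than a cutoff (default 7 residues) with another
protein, and append pseudo-reverse decoys and, optionally, shuffled
entrapment sequences.  After filtering, any protein inference scheme sees
the same unambiguous peptide-to-protein map.

Digestion follows the classic trypsin convention: cleavage C-terminal to
K or R, suppressed when the following residue is P.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import parser as _pyt_parser

from .formats_io import DECOY_PREFIX, ENTRAPMENT_PREFIX

__all__ = [
    "ProteinEntry",
    "tryptic_digest",
    "cleavage_segments",
    "filter_shared_peptides",
    "pseudoreverse_decoys",
    "shuffled_entrapment",
    "read_fasta",
    "write_fasta",
]

# Plain trypsin: cut after K/R unless the next residue is P.
TRYPSIN_RULE = r"[KR](?=[^P])"

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | set("XBZU")

_SPECIES_TAG_RE = re.compile(r"_([A-Z0-9]+)$")


@dataclass(frozen=True)
class ProteinEntry:
    """One FASTA entry; species tag parsed from a UniProt-style suffix."""

    accession: str
    description: str
    sequence: str
    species_tag: str | None = None
    is_decoy: bool = False
    is_entrapment: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residue characters: {sorted(bad)}")


def species_tag_of(accession: str) -> str | None:
    """UniProt-convention species suffix (e.g. ALBU_HUMAN -> HUMAN)."""
    match = _SPECIES_TAG_RE.search(accession)
    return match.group(1) if match else None


def make_entry(accession: str, sequence: str, description: str = "") -> ProteinEntry:
    return ProteinEntry(
        accession=accession,
        description=description,
        sequence=sequence,
        species_tag=species_tag_of(accession),
        is_decoy=accession.startswith(DECOY_PREFIX),
        is_entrapment=accession.startswith(ENTRAPMENT_PREFIX),
    )


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue characters: {sorted(bad)}")


def tryptic_digest(
    sequence: str, min_len: int = 1, max_missed_cleavages: int = 0
) -> list[str]:
    """In-silico tryptic peptides of ``sequence``, in positional order.

    Cleaves C-terminal to K/R except before P; peptides shorter than
    ``min_len`` are dropped; missed-cleavage products up to the stated count
    are included.
    """
    _validate_sequence(sequence)
    pieces = _pyt_parser.icleave(
        sequence,
        TRYPSIN_RULE,
        missed_cleavages=max_missed_cleavages,
        min_length=max(min_len, 1),
    )
    return [pep for _, pep in pieces]


def cleavage_segments(sequence: str) -> list[str]:
    """The zero-missed-cleavage partition of ``sequence``.

    Concatenating the segments reconstructs the input; used by decoy and
    entrapment generation to permute within peptide boundaries.
    """
    _validate_sequence(sequence)
    return [pep for _, pep in _pyt_parser.icleave(sequence, TRYPSIN_RULE, 0, 1)]


def _shared_peptide_index(
    entries: Sequence[ProteinEntry],
    min_shared_len: int,
    il_equivalence: bool,
) -> dict[str, set[str]]:
    """peptide (longer than cutoff) -> set of accessions containing it."""
    index: dict[str, set[str]] = {}
    for entry in entries:
        peptides = {
            pep
            for pep in tryptic_digest(entry.sequence, min_len=min_shared_len + 1)
        }
        for pep in peptides:
            key = pep.replace("L", "I") if il_equivalence else pep
            index.setdefault(key, set()).add(entry.accession)
    return index


def filter_shared_peptides(
    entries: Sequence[ProteinEntry],
    min_shared_len: int = 7,
    *,
    il_equivalence: bool = False,
) -> tuple[list[ProteinEntry], list[dict]]:
    """Remove every protein that shares a long tryptic peptide with another.

    Two proteins "share" a peptide when a zero-missed-cleavage tryptic
    peptide strictly longer than ``min_shared_len`` residues occurs in both.
    All members of a sharing cluster are removed (keeping one member would be
    a protein-inference choice this harmonization deliberately avoids).

    Returns the retained entries and a removal report: one dict per removed
    accession with a witness shared peptide and a partner accession.
    """
    accs = [e.accession for e in entries]
    if len(set(accs)) != len(accs):
        raise ValueError("accessions must be unique")
    index = _shared_peptide_index(entries, min_shared_len, il_equivalence)
    witness: dict[str, tuple[str, str]] = {}
    for pep, owners in index.items():
        if len(owners) > 1:
            owner_list = sorted(owners)
            for acc in owner_list:
                if acc not in witness:
                    partner = next(o for o in owner_list if o != acc)
                    witness[acc] = (pep, partner)
    retained = [e for e in entries if e.accession not in witness]
    report = [
        {"accession": acc, "shared_peptide": pep, "partner": partner}
        for acc, (pep, partner) in sorted(witness.items())
    ]
    return retained, report


def _permute_within_peptides(sequence: str, permute) -> str:
    """Apply ``permute`` to each tryptic segment, keeping a C-terminal K/R fixed."""
    out: list[str] = []
    for segment in cleavage_segments(sequence):
        if len(segment) > 1 and segment[-1] in "KR":
            out.append(permute(segment[:-1]) + segment[-1])
        else:
            out.append(permute(segment))
    return "".join(out)


def pseudoreverse_decoys(
    entries: Sequence[ProteinEntry], decoy_prefix: str = DECOY_PREFIX
) -> list[ProteinEntry]:
    """One pseudo-reverse decoy per target protein.

    Within each tryptic peptide the residues are reversed while the
    C-terminal K/R stays in place, preserving digestion properties of the
    target database.
    """
    decoys: list[ProteinEntry] = []
    for entry in entries:
        if entry.is_decoy:
            raise ValueError("input entries must be targets, not decoys")
        decoys.append(
            ProteinEntry(
                accession=decoy_prefix + entry.accession,
                description=f"pseudo-reverse of {entry.accession}",
                sequence=_permute_within_peptides(
                    entry.sequence, lambda s: s[::-1]
                ),
                species_tag=entry.species_tag,
                is_decoy=True,
                is_entrapment=False,
            )
        )
    return decoys


def shuffled_entrapment(
    entries: Sequence[ProteinEntry],
    multiplier: int = 1,
    seed: int = 0,
    entrapment_prefix: str = ENTRAPMENT_PREFIX,
) -> list[ProteinEntry]:
    """Shuffled entrapment proteins: ``multiplier`` per-peptide shuffles of
    each target, C-terminal K/R fixed, deterministic for a fixed seed."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = random.Random(seed)

    def shuffle(segment: str) -> str:
        chars = list(segment)
        rng.shuffle(chars)
        return "".join(chars)

    out: list[ProteinEntry] = []
    for copy in range(1, multiplier + 1):
        for entry in entries:
            out.append(
                ProteinEntry(
                    accession=f"{entrapment_prefix}{copy}_{entry.accession}",
                    description=f"shuffled entrapment of {entry.accession}",
                    sequence=_permute_within_peptides(entry.sequence, shuffle),
                    species_tag=entry.species_tag,
                    is_decoy=False,
                    is_entrapment=True,
                )
            )
    return out


def read_fasta(path) -> list[ProteinEntry]:
    """Read a FASTA database; the accession is the first header token."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        description = record.description
        if description.startswith(record.id):
            description = description[len(record.id) :].strip()
        entries.append(make_entry(record.id, str(record.seq).upper(), description))
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")
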