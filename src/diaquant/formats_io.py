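"""Reading and writing the tables the quantification engine touches.

The native input format is a Triqler-style tab-separated PSM table with
columns ``run``, ``condition``, ``charge``, ``searchScore``, ``intensity``,
``peptide`` and ``proteins``.  Converter dialects are provided for
OpenSwath+PyProphet exports (identification error probability in ``m_score``)
and DIA-NN reports (``Q.Value``); for those, the search score is produced by
a negative log-transform of the error-probability column so that larger
scores always mean more confident identifications.

Intensities are extracted-ion-chromatogram (XIC) areas in arbitrary units.
Several upstream tools emit ``0`` for "not quantified", so both an empty
field and ``0`` are read as missing; missing values are written back as
empty fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "PsmRecord",
    "QuantTable",
    "FormatError",
    "read_search_results",
    "to_search_score",
    "write_results",
    "read_results",
    "write_search_results",
    "DECOY_PREFIX",
    "ENTRAPMENT_PREFIX",
]

#: Accession prefix marking decoy proteins (configurable per call).
DECOY_PREFIX = "decoy_"
#: Accession prefix marking shuffled entrapment proteins.
ENTRAPMENT_PREFIX = "entrap_"

#: Default separator between multiple protein accessions in one field.
PROTEIN_SEPARATOR = ";"


class FormatError(ValueError):
    """Raised when an input table does not conform to its dialect."""


@dataclass(frozen=True)
class PsmRecord:
    """A single peptide-spectrum-match observation.

    ``search_score`` must reflect increasing certainty in the identification;
    ``intensity`` is ``None`` when the precursor was not quantified in the
    run (a missing value, later handled by the censored-normal model).
    """

    run_id: str
    condition: str
    charge: int
    search_score: float
    intensity: float | None
    peptide: str
    protein_ids: tuple[str, ...]
    is_decoy: bool = False
    is_entrapment: bool = False

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError("protein_ids must be non-empty")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be missing or >= 0")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


@dataclass
class QuantTable:
    """An ordered collection of :class:`PsmRecord` plus run/condition design."""

    records: list[PsmRecord] = field(default_factory=list)

    @property
    def runs(self) -> list[str]:
        """Unique run ids in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.run_id, None)
        return list(seen)

    @property
    def conditions(self) -> dict[str, str]:
        """Mapping run id -> condition label."""
        out: dict[str, str] = {}
        for rec in self.records:
            out.setdefault(rec.run_id, rec.condition)
        return out

    @property
    def n_samples_per_condition(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cond in self.conditions.values():
            counts[cond] = counts.get(cond, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QuantTable) and self.records == other.records

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view (one row per record); intensity NaN when missing."""
        return pd.DataFrame(
            {
                "run": [r.run_id for r in self.records],
                "condition": [r.condition for r in self.records],
                "charge": [r.charge for r in self.records],
                "searchScore": [r.search_score for r in self.records],
                "intensity": [
                    math.nan if r.intensity is None else r.intensity
                    for r in self.records
                ],
                "peptide": [r.peptide for r in self.records],
                "proteins": [
                    PROTEIN_SEPARATOR.join(r.protein_ids) for r in self.records
                ],
                "is_decoy": [r.is_decoy for r in self.records],
                "is_entrapment": [r.is_entrapment for r in self.records],
            }
        )


def to_search_score(error_probability: float, base: float = 10.0) -> float:
    """Negative log-transform of an identification error probability.

    Returns ``-log_base(error_probability)``, strictly decreasing in its
    argument; with the default base 10 an error probability of 1% maps to a
    score of 2.0.
    """
    if not (0.0 < error_probability <= 1.0):
        raise ValueError(
            f"error probability must be in (0, 1], got {error_probability!r}"
        )
    if base <= 1.0:
        raise ValueError("log base must be > 1")
    if base == 10.0:  # correctly rounded, so 0.01 -> 2.0 exactly
        return -math.log10(error_probability)
    if base == 2.0:
        return -math.log2(error_probability)
    return -math.log(error_probability, base)


# Column layout per dialect: canonical field -> column name in the file.
_DIALECTS: dict[str, dict[str, str]] = {
    "triqler-tsv": {
        "run": "run",
        "condition": "condition",
        "charge": "charge",
        "score": "searchScore",
        "intensity": "intensity",
        "peptide": "peptide",
        "proteins": "proteins",
    },
    "openswath-pyprophet": {
        "run": "filename",
        "condition": "condition",
        "charge": "Charge",
        "score": "m_score",  # error probability; converted via to_search_score
        "intensity": "Intensity",
        "peptide": "FullPeptideName",
        "proteins": "ProteinName",
    },
    "diann-report": {
        "run": "Run",
        "condition": "condition",
        "charge": "Precursor.Charge",
        "score": "Q.Value",  # error probability; converted via to_search_score
        "intensity": "Precursor.Quantity",
        "peptide": "Stripped.Sequence",
        "proteins": "Protein.Ids",
    },
}

# Columns whose presence defines the dialect but that carry an
# error probability rather than a ready-made score.
_ERROR_PROBABILITY_DIALECTS = {"openswath-pyprophet", "diann-report"}

# Extra columns that must be present even if not consumed.
_EXTRA_MANDATORY = {"diann-report": ["CScore"]}


def _parse_intensity(raw: object, line_no: int) -> float | None:
    """Empty field and 0 both mean missing; anything non-numeric is an error."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(
            f"non-numeric intensity {text!r} on line {line_no}"
        ) from exc
    if value == 0.0:
        return None
    return value


def read_search_results(
    path,
    dialect: str = "triqler-tsv",
    *,
    log_base: float = 10.0,
    protein_separator: str = PROTEIN_SEPARATOR,
    decoy_prefix: str = DECOY_PREFIX,
    entrapment_prefix: str = ENTRAPMENT_PREFIX,
) -> QuantTable:
    """Read a PSM-level search-result table into a :class:`QuantTable`.

    For the ``openswath-pyprophet`` and ``diann-report`` dialects the search
    score is ``-log_base`` of the error-probability column (``m_score`` /
    ``Q.Value``); the native ``triqler-tsv`` dialect carries the score
    directly.
    """
    if dialect not in _DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    cols = _DIALECTS[dialect]
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = list(cols.values()) + _EXTRA_MANDATORY.get(dialect, [])
    for column in mandatory:
        if column not in frame.columns:
            raise FormatError(
                f"missing mandatory column {column!r} for dialect {dialect!r}"
            )

    records: list[PsmRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        line_no = idx + 2  # header occupies line 1
        raw_score = float(row_map[cols["score"]])
        if dialect in _ERROR_PROBABILITY_DIALECTS:
            score = to_search_score(raw_score, base=log_base)
        else:
            score = raw_score
        proteins = tuple(
            p.strip()
            for p in str(row_map[cols["proteins"]]).split(protein_separator)
            if p.strip()
        )
        if not proteins:
            raise FormatError(f"empty protein field on line {line_no}")
        records.append(
            PsmRecord(
                run_id=str(row_map[cols["run"]]),
                condition=str(row_map[cols["condition"]]),
                charge=int(float(row_map[cols["charge"]])),
                search_score=score,
                intensity=_parse_intensity(row_map[cols["intensity"]], line_no),
                peptide=str(row_map[cols["peptide"]]),
                protein_ids=proteins,
                is_decoy=all(p.startswith(decoy_prefix) for p in proteins),
                is_entrapment=all(
                    p.startswith(entrapment_prefix) for p in proteins
                ),
            )
        )
    return QuantTable(records)


def write_search_results(table: QuantTable, path) -> None:
    """Write a :class:`QuantTable` in the native triqler-tsv dialect.

    Floats are written with ``repr`` so that read(write(T)) == T.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "run\tcondition\tcharge\tsearchScore\tintensity\tpeptide\tproteins\n"
        )
        for rec in table.records:
            intensity = "" if rec.intensity is None else repr(float(rec.intensity))
            handle.write(
                "\t".join(
                    [
                        rec.run_id,
                        rec.condition,
                        str(rec.charge),
                        repr(float(rec.search_score)),
                        intensity,
                        rec.peptide,
                        PROTEIN_SEPARATOR.join(rec.protein_ids),
                    ]
                )
                + "\n"
            )


_RESULT_FIXED_COLUMNS = [
    "protein",
    "species",
    "n_peptides",
    "log2_fold_change",
    "differential_pep",
    "q_value",
]


def write_results(results: Sequence, path) -> None:
    """Write protein-level results as a tab-separated table.

    Fixed column order: protein, species, n_peptides, one
    ``abundance.<run>`` column per run (MAP log10 abundance), log2
    fold-change MAP, differential PEP, q-value.  Values round-trip at full
    precision through :func:`read_results`.
    """
    run_order: dict[str, None] = {}
    for res in results:
        for run in res.map_abundance_per_sample:
            run_order.setdefault(run, None)
    runs = list(run_order)
    header = _RESULT_FIXED_COLUMNS[:3] + [f"abundance.{r}" for r in runs] + (
        _RESULT_FIXED_COLUMNS[3:]
    )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(header) + "\n")
        for res in results:
            if not (0.0 <= res.differential_pep <= 1.0):
                raise ValueError("differential_pep outside [0, 1]")
            if not (0.0 <= res.q_value <= 1.0):
                raise ValueError("q_value outside [0, 1]")
            row = [
                res.protein_id,
                res.species_tag or "",
                str(res.n_peptides),
            ]
            for run in runs:
                value = res.map_abundance_per_sample.get(run)
                row.append("" if value is None else repr(value))
            row += [
                repr(res.log2_fc_map),
                repr(res.differential_pep),
                repr(res.q_value),
            ]
            handle.write("\t".join(row) + "\n")


def read_results(path) -> list:
    """Read back a table written by :func:`write_results`."""
    from .model import ProteinResult  # local import avoids a cycle

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    runs = [c[len("abundance.") :] for c in frame.columns if c.startswith("abundance.")]
    out: list[ProteinResult] = []
    for _, row in frame.iterrows():
        abundances = {
            run: float(row[f"abundance.{run}"])
            for run in runs
            if row[f"abundance.{run}"] != ""
        }
        out.append(
            ProteinResult(
                protein_id=row["protein"],
                species_tag=row["species"] or None,
                n_peptides=int(row["n_peptides"]),
                map_abundance_per_sample=abundances,
                log2_fc_map=float(row["log2_fold_change"]),
                differential_pep=float(row["differential_pep"]),
                q_value=float(row["q_value"]),
            )
        )
    return out
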