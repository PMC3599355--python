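"""Candidate protein records and curation configuration.

A :class:`ProteinRecord` is one row of a mined-candidate table: an accession,
the source organism, the database's predicted function, the experimentally
verified function (empty for uncharacterized candidates) and the percent
identity to the query enzyme used for mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass
class ProteinRecord:
    """One candidate sequence plus its annotation state."""

    accession: str
    organism: str
    residues: str = ""
    predicted_function: str = ""
    defined_function: str = ""
    identity_to_query: float | None = None

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid amino-acid letters {sorted(bad)}"
            )
        if self.identity_to_query is not None and not (
            0.0 <= self.identity_to_query <= 100.0
        ):
            raise ValueError(
                f"{self.accession}: identity {self.identity_to_query} outside [0, 100]"
            )

    @property
    def is_reference(self) -> bool:
        """True when the record's function is experimentally verified."""
        return bool(self.defined_function.strip())

    def with_residues(self, residues: str) -> "ProteinRecord":
        return replace(self, residues=residues)


@dataclass(frozen=True)
class CurationConfig:
    """Screening thresholds for the mined-candidate curation step.

    ``identity_low``/``identity_high`` bound the retained percent-identity
    window; ``max_per_identity`` caps how many uncharacterized records may
    share one integer-rounded identity value; the catalytic-triad check is
    applied only to records annotated ``unnamed protein product``.
    """

    identity_low: float = 30.0
    identity_high: float = 90.0
    max_per_identity: int = 2
    triad_required: bool = True
    keep_defined_regardless: bool = True
    triad_min_spacing: int = 10
    triad_max_spacing: int = 400

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_low < self.identity_high <= 100.0):
            raise ValueError("require 0 <= identity_low < identity_high <= 100")
        if self.max_per_identity < 1:
            raise ValueError("max_per_identity must be >= 1")
        if self.triad_min_spacing < 1 or self.triad_max_spacing < self.triad_min_spacing:
            raise ValueError("invalid triad spacing window")

    @classmethod
    def passthrough(cls) -> "CurationConfig":
        """A configuration under which no record is ever removed.

        Used when the input table is already a final, post-mining candidate
        set (e.g. synthetic families, or a published table transcribed after
        screening) so the curation stage acts as validation only.
        """
        return cls(
            identity_low=0.0,
            identity_high=100.0,
            max_per_identity=10**9,
            triad_required=False,
        )


@dataclass
class CuratedSet:
    """Curation survivors plus an audit trail of removals.

    ``audit`` maps each removed accession to the first rule that removed it
    (``identity_window``, ``identity_cap``, ``species_dedup`` or
    ``missing_triad``).
    """

    records: list[ProteinRecord] = field(default_factory=list)
    audit: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    @property
    def references(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.is_reference]
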