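"""Screening of mined nitrilase candidates.

The mining workflow this reproduces: a BLASTP hit table against a query
enzyme with known substrate specificity is screened by (1) a percent-identity
window (too-similar and too-distant hits removed, with a cap on how many hits
may share one identity value), (2) source-organism deduplication (one record
per identical sequence per organism; distinct loci from one strain all kept),
and (3) a Glu-Lys-Cys catalytic-triad scan applied to hits annotated only as
"unnamed protein product". Records whose function is experimentally defined
are kept unconditionally — they anchor the later clade designation.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .records import CuratedSet, CurationConfig, ProteinRecord

REFERENCE_TABLE_COLUMNS = (
    "accession",
    "organism",
    "predicted_function",
    "defined_function",
    "identity_pct",
    "citation",
)


class ReferenceTableError(ValueError):
    """Raised for schema or content problems in a reference-annotation table."""


def load_reference_table(path: str | Path) -> list[ProteinRecord]:
    """Load a reference-annotation TSV into :class:`ProteinRecord` objects.

    The table schema is
    ``accession  organism  predicted_function  defined_function  identity_pct
    citation`` (tab-separated, UTF-8). An empty ``defined_function`` marks an
    uncharacterized candidate. Row order is preserved.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ReferenceTableError(f"{path}: empty file, expected header") from None
        if tuple(h.strip() for h in header) != REFERENCE_TABLE_COLUMNS:
            raise ReferenceTableError(
                f"{path}: header {header!r} does not match "
                f"{list(REFERENCE_TABLE_COLUMNS)!r}"
            )
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 5:
                raise ReferenceTableError(f"{path}: row {lineno} has {len(row)} fields")
            accession = row[0].strip()
            if not accession:
                raise ReferenceTableError(f"{path}: row {lineno} missing accession")
            if accession in seen:
                raise ReferenceTableError(
                    f"{path}: row {lineno} duplicate accession {accession}"
                )
            seen.add(accession)
            identity_raw = row[4].strip()
            identity: float | None = None
            if identity_raw:
                try:
                    identity = float(identity_raw)
                except ValueError:
                    raise ReferenceTableError(
                        f"{path}: row {lineno} malformed identity {identity_raw!r}"
                    ) from None
            try:
                records.append(
                    ProteinRecord(
                        accession=accession,
                        organism=row[1].strip(),
                        predicted_function=row[2].strip(),
                        defined_function=row[3].strip(),
                        identity_to_query=identity,
                    )
                )
            except ValueError as exc:
                raise ReferenceTableError(f"{path}: row {lineno}: {exc}") from None
    return records


def write_reference_table(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records back to the reference-annotation TSV schema."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REFERENCE_TABLE_COLUMNS)
        for r in records:
            identity = "" if r.identity_to_query is None else format(r.identity_to_query, "g")
            writer.writerow(
                [r.accession, r.organism, r.predicted_function, r.defined_function,
                 identity, "synthetic" if r.accession.startswith("SYN_") else ""]
            )


def attach_sequences(
    records: list[ProteinRecord], sequences: dict[str, str]
) -> list[ProteinRecord]:
    """Attach FASTA residues to records by accession; missing ids are an error."""
    missing = [r.accession for r in records if r.accession not in sequences]
    if missing:
        raise KeyError(f"no sequence for accessions: {missing}")
    return [r.with_residues(sequences[r.accession]) for r in records]


def _require_identities(records: list[ProteinRecord]) -> None:
    unset = [r.accession for r in records if r.identity_to_query is None]
    if unset:
        raise ValueError(f"identity_to_query unset for: {unset}")


def filter_identity_window(
    records: list[ProteinRecord], cfg: CurationConfig
) -> list[ProteinRecord]:
    """Keep uncharacterized records with identity in [low, high].

    Records with an experimentally defined function are retained regardless
    when ``keep_defined_regardless`` is set — this is how the 100%-identity
    query itself survives the >90% removal rule.
    """
    _require_identities(records)
    kept = []
    for r in records:
        if cfg.keep_defined_regardless and r.is_reference:
            kept.append(r)
        elif cfg.identity_low <= r.identity_to_query <= cfg.identity_high:
            kept.append(r)
    return kept


def cap_identity_duplicates(
    records: list[ProteinRecord], cfg: CurationConfig
) -> list[ProteinRecord]:
    """Keep at most ``max_per_identity`` uncharacterized records per identity.

    Identity ties are compared at integer-percent resolution (the granularity
    at which mined identities are reported). Earliest rows win; reference
    records neither count against the cap nor are removed by it.
    """
    _require_identities(records)
    counts: dict[int, int] = {}
    kept = []
    for r in records:
        if cfg.keep_defined_regardless and r.is_reference:
            kept.append(r)
            continue
        key = int(round(r.identity_to_query))
        counts[key] = counts.get(key, 0) + 1
        if counts[key] <= cfg.max_per_identity:
            kept.append(r)
    return kept


def dedup_by_species(
    records: list[ProteinRecord], cfg: CurationConfig | None = None
) -> list[ProteinRecord]:
    """Collapse records sharing an organism string AND identical residues.

    Distinct sequences from the same strain are different loci and all
    survive; only true per-organism sequence duplicates are collapsed (first
    occurrence wins). Reference records are never collapsed away.
    """
    if any(not r.organism for r in records):
        raise ValueError("dedup_by_species requires non-empty organism strings")
    keep_refs = cfg.keep_defined_regardless if cfg is not None else True
    seen: set[tuple[str, str]] = set()
    kept = []
    for r in records:
        key = (r.organism, r.residues)
        if key in seen and not (keep_refs and r.is_reference):
            continue
        seen.add(key)
        kept.append(r)
    return kept


def scan_catalytic_triad(
    residues: str,
    min_spacing: int = 1,
    max_spacing: int | None = None,
) -> tuple[bool, tuple[int, int, int] | None]:
    """Scan for the nitrilase-superfamily Glu-Lys-Cys catalytic triad.

    Returns ``(found, positions)`` where positions are 1-based indices of the
    first E < K < C triple whose E-K and K-C spacings both lie within
    ``[min_spacing, max_spacing]``. The default window is unconstrained; the
    curation step narrows it (see :class:`CurationConfig`). This is an
    ordered-occurrence heuristic, not a sequence-profile match.
    """
    if not residues:
        raise ValueError("empty sequence")
    seq = residues.upper()
    hi = max_spacing if max_spacing is not None else len(seq)
    e_pos = [i for i, c in enumerate(seq) if c == "E"]
    k_pos = [i for i, c in enumerate(seq) if c == "K"]
    c_pos = [i for i, c in enumerate(seq) if c == "C"]
    for e in e_pos:
        for k in k_pos:
            gap_ek = k - e
            if gap_ek < min_spacing:
                continue
            if gap_ek > hi:
                break
            for c in c_pos:
                gap_kc = c - k
                if gap_kc < min_spacing:
                    continue
                if gap_kc > hi:
                    break
                return True, (e + 1, k + 1, c + 1)
    return False, None


def curate(records: list[ProteinRecord], cfg: CurationConfig | None = None) -> CuratedSet:
    """Apply the full screening cascade and record why each casualty fell.

    Order: identity window -> same-identity cap -> species dedup -> triad scan
    (triad only for records annotated "unnamed protein product", and only when
    ``triad_required``). The audit names the first rule that removed each
    record. Applying ``curate`` twice is equivalent to applying it once.
    """
    cfg = cfg or CurationConfig()
    audit: dict[str, str] = {}
    if not records:
        return CuratedSet([], audit)

    stage1 = filter_identity_window(records, cfg)
    survivors = {r.accession for r in stage1}
    for r in records:
        if r.accession not in survivors:
            audit[r.accession] = "identity_window"

    stage2 = cap_identity_duplicates(stage1, cfg)
    survivors = {r.accession for r in stage2}
    for r in stage1:
        if r.accession not in survivors:
            audit[r.accession] = "identity_cap"

    stage3 = dedup_by_species(stage2, cfg)
    survivors = {r.accession for r in stage3}
    for r in stage2:
        if r.accession not in survivors:
            audit[r.accession] = "species_dedup"

    stage4 = []
    for r in stage3:
        if (
            cfg.triad_required
            and not r.is_reference
            and r.predicted_function.lower() == "unnamed protein product"
        ):
            if not r.residues:
                raise ValueError(f"{r.accession}: triad scan requires residues")
            found, _ = scan_catalytic_triad(
                r.residues, cfg.triad_min_spacing, cfg.triad_max_spacing
            )
            if not found:
                audit[r.accession] = "missing_triad"
                continue
        stage4.append(r)

    return CuratedSet(stage4, audit)
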