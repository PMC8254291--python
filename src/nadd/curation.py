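"""Curation of raw per-assay activity measurements into pActivity tables.

Raw bioactivity tables (one measurement per row: compound id, SMILES, value,
unit, qualifier) are noisy: qualified values ("<"/">"), mixed units, replicate
measurements that disagree, the same structure registered under several ids,
and oversized molecules. This module applies a fixed, ordered sequence of
cleaning steps and returns a per-assay table of one pActivity per unique
structure, together with an auditable per-step record count report.

The cleaning steps, in order:

0. structure standardization (drop unparseable SMILES),
1. optional endpoint allowlist,
2. drop records with missing values, "<"/">" qualifiers, or nonpositive values,
3. drop records whose unit is not in the recognised closed set,
4. convert to pActivity = -log10(molar value); drop values outside the open
   interval (2, 11) log units (i.e. weaker than 10 mM or stronger than 10 pM)
   and records whose unit claims the value is already logged,
5. per compound id: drop the compound if its replicate pActivities span more
   than 2.5 log units, otherwise keep the median,
6. for distinct ids sharing one standardized structure, keep the entry with
   the highest pActivity,
7. drop structures with more than 70 heavy atoms,
8. drop the whole assay if fewer than 25 unique compounds remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Molar conversion factors for the recognised unit vocabulary.  "logged"
#: marks values reported as pActivity with a (contradictory) unit; such
#: records are recognised in step 3 but discarded in step 4.
UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}
KNOWN_UNITS = frozenset(UNIT_FACTORS) | {"logged"}

STEP_NAMES = (
    "standardize_structures",
    "endpoint_selection",
    "drop_qualified_missing_negative",
    "drop_undefined_units",
    "to_pactivity_range",
    "replicate_spread",
    "duplicate_structures",
    "heavy_atom_limit",
    "min_assay_size",
)


@dataclass(frozen=True)
class ActivityRecord:
    """One raw assay measurement as it enters curation."""

    compound_id: str
    smiles: str
    assay_id: str
    value: float | None
    unit: str
    qualifier: str = "="
    endpoint: str = ""


@dataclass(frozen=True)
class CuratedEntry:
    compound_id: str
    smiles: str  # standardized canonical SMILES
    pact: float  # log units


@dataclass
class CuratedAssay:
    """One pActivity per unique standardized structure in one assay."""

    assay_id: str
    entries: list[CuratedEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pact_by_id(self) -> dict[str, float]:
        return {e.compound_id: e.pact for e in self.entries}

    @property
    def smiles_by_id(self) -> dict[str, str]:
        return {e.compound_id: e.smiles for e in self.entries}

    def to_records(self) -> list[ActivityRecord]:
        """Re-express curated entries as molar measurements (unit M)."""
        return [
            ActivityRecord(e.compound_id, e.smiles, self.assay_id,
                           10.0 ** (-e.pact), "M", "=")
            for e in self.entries
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.compound_id, e.smiles, e.pact) for e in self.entries],
            columns=["compound_id", "smiles", "pact"],
        )


@dataclass
class FilterReport:
    """Ordered (step_name, records_in, records_out) counts for one assay."""

    assay_id: str
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"step {name}: records_out {n_out} > records_in {n_in}")
        self.steps.append((name, n_in, n_out))

    def count_after(self, name: str) -> int:
        for step, _, n_out in self.steps:
            if step == name:
                return n_out
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "records_in", "records_out"]).assign(
            assay_id=self.assay_id
        )


@dataclass
class CurationConfig:
    min_assay_size: int = 25
    max_heavy_atoms: int = 70
    replicate_spread_max: float = 2.5
    pact_min: float = 2.0   # open bound: 10 mM
    pact_max: float = 11.0  # open bound: 10 pM
    endpoint_allowlist: frozenset[str] | None = None
    canonical_tautomer: bool = True


@lru_cache(maxsize=200_000)
def _standardize_cached(smiles: str, canonical_tautomer: bool) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        if canonical_tautomer:
            mol = rdMolStandardize.TautomerEnumerator().Canonicalize(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def standardize_structure(smiles: str, canonical_tautomer: bool = True) -> str:
    """Return the standardized canonical SMILES (neutralized, canonical tautomer).

    Idempotent: ``standardize_structure(standardize_structure(s)) ==
    standardize_structure(s)``.  Raises ``ValueError`` for unparseable input.
    """
    out = _standardize_cached(smiles, canonical_tautomer)
    if out is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    return out


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    # heavy atom = atomic number > 1
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def to_pactivity(value: float, unit: str) -> float:
    """Convert a raw activity in the given unit to pActivity = -log10(mol/L)."""
    if unit not in UNIT_FACTORS:
        raise ValueError(f"unit {unit!r} has no molar conversion")
    if value is None or not math.isfinite(value) or value <= 0:
        raise ValueError("negative/zero value")
    return -math.log10(value * UNIT_FACTORS[unit])


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def curate_assay(
    records: Sequence[ActivityRecord], config: CurationConfig | None = None
) -> tuple[CuratedAssay | None, FilterReport]:
    """Run the full cleaning sequence on one assay's raw records.

    Returns ``(assay, report)``; ``assay`` is ``None`` when fewer than
    ``config.min_assay_size`` unique compounds survive.
    """
    cfg = config or CurationConfig()
    assay_ids = {r.assay_id for r in records}
    if len(assay_ids) > 1:
        raise ValueError(f"records span multiple assays: {sorted(assay_ids)}")
    assay_id = next(iter(assay_ids)) if assay_ids else "<empty>"
    report = FilterReport(assay_id)

    # step 0: structure standardization; unparseable records dropped
    std: list[tuple[ActivityRecord, str]] = []
    for r in records:
        s = _standardize_cached(r.smiles, cfg.canonical_tautomer)
        if s is not None:
            std.append((r, s))
    report.add("standardize_structures", len(records), len(std))

    # step 1: endpoint allowlist (manual selection surrogate)
    n_in = len(std)
    if cfg.endpoint_allowlist is not None:
        std = [(r, s) for r, s in std if r.endpoint in cfg.endpoint_allowlist]
    report.add("endpoint_selection", n_in, len(std))

    # step 2: missing values, qualified records, nonpositive values
    kept2 = [
        (r, s)
        for r, s in std
        if not _is_missing(r.value) and r.qualifier == "=" and r.value > 0
    ]
    report.add("drop_qualified_missing_negative", len(std), len(kept2))

    # step 3: unit must belong to the recognised vocabulary
    kept3 = [(r, s) for r, s in kept2 if r.unit in KNOWN_UNITS]
    report.add("drop_undefined_units", len(kept2), len(kept3))

    # step 4: unit conversion; discard pre-logged records and values outside
    # the open (pact_min, pact_max) window
    converted: list[tuple[str, str, float]] = []  # (compound_id, std smiles, pact)
    for r, s in kept3:
        if r.unit == "logged":
            continue
        pact = to_pactivity(r.value, r.unit)
        if cfg.pact_min < pact < cfg.pact_max:
            converted.append((r.compound_id, s, pact))
    report.add("to_pactivity_range", len(kept3), len(converted))

    # step 5: replicate handling per compound id
    by_id: dict[str, list[tuple[str, float]]] = {}
    for cid, s, p in converted:
        by_id.setdefault(cid, []).append((s, p))
    merged: list[tuple[str, str, float]] = []
    for cid, rows in by_id.items():
        pacts = sorted(p for _, p in rows)
        if pacts[-1] - pacts[0] > cfg.replicate_spread_max:
            continue
        median = _median(pacts)
        merged.append((cid, rows[0][0], median))
    report.add("replicate_spread", len(converted), len(merged))

    # step 6: duplicate structures under distinct ids -> keep highest pact
    by_struct: dict[str, tuple[str, str, float]] = {}
    for cid, s, p in merged:
        best = by_struct.get(s)
        if best is None or p > best[2]:
            by_struct[s] = (cid, s, p)
    deduped = list(by_struct.values())
    report.add("duplicate_structures", len(merged), len(deduped))

    # step 7: molecular size limit
    sized = [(cid, s, p) for cid, s, p in deduped if heavy_atom_count(s) <= cfg.max_heavy_atoms]
    report.add("heavy_atom_limit", len(deduped), len(sized))

    # step 8: minimum assay size
    if len(sized) < cfg.min_assay_size:
        report.add("min_assay_size", len(sized), 0)
        return None, report
    report.add("min_assay_size", len(sized), len(sized))

    entries = [CuratedEntry(cid, s, p) for cid, s, p in sorted(sized)]
    return CuratedAssay(assay_id, entries), report


def _median(sorted_vals: list[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


# ---------------------------------------------------------------------------
# tabular I/O

RAW_COLUMNS = ["compound_id", "smiles", "assay_id", "value", "unit", "qualifier", "endpoint"]


def records_from_frame(df: pd.DataFrame) -> list[ActivityRecord]:
    """Build ActivityRecords from a DataFrame with the raw-table columns."""
    recs = []
    for row in df.itertuples(index=False):
        value = getattr(row, "value", None)
        value = None if _is_missing(value) else float(value)
        recs.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                assay_id=str(row.assay_id),
                value=value,
                unit=str(row.unit),
                qualifier=str(getattr(row, "qualifier", "=")),
                endpoint=str(getattr(row, "endpoint", "")),
            )
        )
    return recs


def records_to_frame(records: Iterable[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=RAW_COLUMNS)


def read_raw_table(path) -> dict[str, list[ActivityRecord]]:
    """Read a raw measurement CSV/TSV and group records per assay."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"compound_id", "smiles", "assay_id", "value", "unit"} - set(df.columns)
    if missing:
        raise ValueError(f"raw table missing columns: {sorted(missing)}")
    out: dict[str, list[ActivityRecord]] = {}
    for assay_id, sub in df.groupby("assay_id", sort=True):
        out[str(assay_id)] = records_from_frame(sub)
    return out
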