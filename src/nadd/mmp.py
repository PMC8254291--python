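"""Matched-molecular-pair indexing by single acyclic bond cuts.

A matched molecular pair (MMP) is two compounds that differ by one localized
structural transformation while sharing a constant context. Pairs are found
by fragmenting every molecule at each single, acyclic bond between heavy
atoms (the Hussain–Rea single-cut scheme): each cut yields a *context*
fragment and a *variable* fragment, both carrying one ``[*]`` attachment
point. Two molecules whose fragmentations share a context key but differ in
the variable key form a pair.

Transformations exchanging more than one third of a molecule's heavy atoms
are discarded (`max_variable_fraction`), since near-total exchanges say
little about local SAR and tend to change the binding mode outright.
Hydrogen replacements (H -> fragment) are not generated: only existing bonds
between heavy atoms are cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem

DEFAULT_MAX_VARIABLE_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition of a parent molecule."""

    parent_id: str
    context_key: str          # canonical SMILES of the constant part, one [*]
    variable_key: str         # canonical SMILES of the cut-off fragment, one [*]
    variable_heavy_atoms: int


@dataclass(frozen=True)
class MatchedPair:
    """Two compounds related by one transformation within a shared context.

    The direction is canonical: ``variable_from <= variable_to``
    lexicographically, with ``compound_from`` bearing ``variable_from``.
    """

    compound_from: str
    compound_to: str
    context_key: str
    variable_from: str
    variable_to: str

    @property
    def transformation(self) -> tuple[str, str]:
        return (self.variable_from, self.variable_to)


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


@lru_cache(maxsize=100_000)
def _cut_fragments(smiles: str) -> tuple[tuple[str, int, str, int], ...]:
    """All single acyclic heavy-heavy bond cuts of `smiles`.

    Returns tuples ``(frag_a, heavy_a, frag_b, heavy_b)`` of canonical
    fragment SMILES (with one [*] each) and their heavy atom counts.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True,
                                    dummyLabels=[(0, 0)])
        pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        if len(pieces) != 2:  # pragma: no cover - acyclic cut always splits in two
            continue
        pa, pb = pieces
        cuts.append((Chem.MolToSmiles(pa), _heavy(pa), Chem.MolToSmiles(pb), _heavy(pb)))
    return tuple(cuts)


def fragment(
    smiles: str,
    parent_id: str | None = None,
    max_variable_fraction: float | None = DEFAULT_MAX_VARIABLE_FRACTION,
) -> set[Fragmentation]:
    """Enumerate single-cut fragmentations of one molecule.

    Each cut is emitted with either side playing the variable role, except
    that fragmentations whose variable part exceeds ``max_variable_fraction``
    of the parent's heavy atoms are discarded (pass ``None`` to keep all).
    """
    pid = parent_id if parent_id is not None else smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    n_heavy = _heavy(mol)
    limit = None if max_variable_fraction is None else n_heavy * max_variable_fraction
    out: set[Fragmentation] = set()
    for frag_a, heavy_a, frag_b, heavy_b in _cut_fragments(smiles):
        for ctx, var, var_heavy in ((frag_a, frag_b, heavy_b), (frag_b, frag_a, heavy_a)):
            if limit is not None and var_heavy > limit:
                continue
            out.add(Fragmentation(pid, ctx, var, var_heavy))
    return out


def index_pairs(
    structures: Mapping[str, str],
    max_variable_fraction: float | None = DEFAULT_MAX_VARIABLE_FRACTION,
) -> list[MatchedPair]:
    """Find all matched pairs among ``{compound_id: smiles}``.

    For every context key shared by two or more compounds, all unordered
    compound pairs with distinct variable keys are emitted once, in the
    canonical direction. The result is independent of input ordering.
    """
    by_context: dict[str, list[tuple[str, str]]] = {}
    for cid in sorted(structures):
        for f in fragment(structures[cid], cid, max_variable_fraction):
            by_context.setdefault(f.context_key, []).append((cid, f.variable_key))
    pairs: set[MatchedPair] = set()
    for ctx, members in by_context.items():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            cid_i, var_i = members[i]
            for j in range(i + 1, len(members)):
                cid_j, var_j = members[j]
                if cid_i == cid_j or var_i == var_j:
                    continue
                if var_i <= var_j:
                    pairs.add(MatchedPair(cid_i, cid_j, ctx, var_i, var_j))
                else:
                    pairs.add(MatchedPair(cid_j, cid_i, ctx, var_j, var_i))
    return sorted(pairs, key=lambda p: (p.context_key, p.variable_from,
                                        p.variable_to, p.compound_from, p.compound_to))


def pairs_to_frame(pairs: Iterable[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.compound_from, p.compound_to, p.context_key, p.variable_from, p.variable_to)
         for p in pairs],
        columns=["compound_a", "compound_b", "context", "transformation_from",
                 "transformation_to"],
    )
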