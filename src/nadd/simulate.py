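"""Synthetic combinatorial SAR libraries with known (non)additive structure.

The generator enumerates R-group libraries on a common scaffold under a
Free-Wilson model: the true pActivity of a molecule is a scaffold baseline
plus one additive contribution per substituent. Nonadditivity is injected as
pairwise interaction terms — an extra delta added when two specific
substituents co-occur at two specific sites — so that the ground-truth
ddpAct of every double-transformation cycle is known in closed form and the
whole analysis chain (curation, MMP indexing, cycle assembly, significance
calling, QSAR splits) can be validated without any external data.

Measurement emulation re-expresses the true pActivity as a raw molar value
in a sampled unit, adds i.i.d. Gaussian noise per replicate, and optionally
injects qualified ("<") records and duplicate registrations of the same
structure under a second compound id, to exercise every curation step.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .curation import ActivityRecord

# substituent alphabet: (name, SMILES as attached).  Small groups only, so
# the variable side of every designed transformation stays well under one
# third of the molecule; tautomer-labile groups (e.g. hydroxy next to ring
# nitrogens) are avoided so standardization cannot rewrite the scaffold.
SUBSTITUENT_ALPHABET: tuple[tuple[str, str], ...] = (
    ("methyl", "C"),
    ("ethyl", "CC"),
    ("chloro", "Cl"),
    ("fluoro", "F"),
    ("methoxy", "OC"),
    ("amino", "N"),
    ("bromo", "Br"),
    ("cyano", "C#N"),
)

#: Default scaffolds with 2 and 3 inequivalent attachment sites.
DEFAULT_SCAFFOLDS = {
    2: "[*:1]c1ccc2nc([*:2])ccc2c1",      # disubstituted quinoline
    3: "[*:1]c1ccc2nc([*:2])cc([*:3])c2c1",
}


@dataclass(frozen=True)
class Substituent:
    name: str
    smiles: str            # without attachment point, e.g. "CC"
    contribution: float    # additive effect, log units


@dataclass(frozen=True)
class Site:
    site_id: int           # matches the [*:n] map number on the scaffold
    substituents: tuple[Substituent, ...]


@dataclass(frozen=True)
class NAInjection:
    """Interaction term: ``delta`` added when both substituents co-occur."""

    site_a: int
    substituent_a: str
    site_b: int
    substituent_b: str
    delta: float

    def applies(self, choice: dict[int, str]) -> bool:
        return (choice.get(self.site_a) == self.substituent_a
                and choice.get(self.site_b) == self.substituent_b)


@dataclass(frozen=True)
class FreeWilsonSpec:
    """One combinatorial series: scaffold, sites, per-substituent effects."""

    scaffold: str          # SMILES with [*:1], [*:2], ... attachment points
    sites: tuple[Site, ...]
    baseline: float        # log units
    series_id: str = "S0"

    def __post_init__(self):
        if len(self.sites) < 2:
            raise ValueError("a Free-Wilson series needs at least 2 sites")
        for s in self.sites:
            if len(s.substituents) < 2:
                raise ValueError(f"site {s.site_id} needs at least 2 substituents")


@dataclass(frozen=True)
class LibraryMolecule:
    compound_id: str
    smiles: str
    true_pact: float
    series_id: str
    choice: tuple[tuple[int, str], ...]          # ((site_id, substituent name), ...)
    injections: tuple[NAInjection, ...] = ()     # interactions applying to this molecule


@dataclass(frozen=True)
class GroundTruthCycle:
    """A designed DTC: member compound ids and the exact ddpAct it should show.

    ``c3`` is the doubly-transformed corner carrying both varied substituent
    end points; with one injection of size delta on that corner the cycle's
    ddpAct equals -delta under the canonical statistic, i.e. |ddpAct| = delta.
    """

    compounds: tuple[str, str, str, str]
    na_true: float

    @property
    def is_additive(self) -> bool:
        return abs(self.na_true) < 1e-12


def _attach(scaffold: str, subs: dict[int, str]) -> str:
    """Attach substituent SMILES to the labelled scaffold via molzip."""
    mols = [Chem.MolFromSmiles(scaffold)]
    if mols[0] is None:
        raise ValueError(f"invalid scaffold: {scaffold!r}")
    for site_id, sub_smiles in subs.items():
        frag = Chem.MolFromSmiles(f"[*:{site_id}]{sub_smiles}")
        if frag is None:
            raise ValueError(f"invalid substituent {sub_smiles!r} at site {site_id}")
        mols.append(frag)
    combo = mols[0]
    for m in mols[1:]:
        combo = Chem.CombineMols(combo, m)
    zipped = Chem.molzip(combo)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def enumerate_library(
    spec: FreeWilsonSpec,
    injections: Sequence[NAInjection] = (),
) -> list[LibraryMolecule]:
    """Full combinatorial enumeration with ground-truth pActivities.

    true_pact = baseline + sum of site contributions + sum of applicable
    interaction deltas. Raises if any combination yields invalid chemistry or
    if two combinations collapse to one structure (symmetric scaffold).
    """
    site_ids = [s.site_id for s in spec.sites]
    for inj in injections:
        _check_injection(spec, inj)
    out: list[LibraryMolecule] = []
    seen: dict[str, str] = {}
    for combo in itertools.product(*[s.substituents for s in spec.sites]):
        choice = {sid: sub.name for sid, sub in zip(site_ids, combo)}
        smiles = _attach(spec.scaffold, {sid: sub.smiles for sid, sub in zip(site_ids, combo)})
        cid = spec.series_id + "-" + "_".join(sub.name for sub in combo)
        if smiles in seen:
            raise ValueError(
                f"scaffold symmetry collapses {cid} and {seen[smiles]} to one structure"
            )
        seen[smiles] = cid
        applying = tuple(i for i in injections if i.applies(choice))
        pact = spec.baseline + sum(s.contribution for s in combo) \
            + sum(i.delta for i in applying)
        out.append(
            LibraryMolecule(
                compound_id=cid,
                smiles=smiles,
                true_pact=pact,
                series_id=spec.series_id,
                choice=tuple(sorted(choice.items())),
                injections=applying,
            )
        )
    return out


def _check_injection(spec: FreeWilsonSpec, inj: NAInjection) -> None:
    by_site = {s.site_id: {sub.name for sub in s.substituents} for s in spec.sites}
    for site, name in ((inj.site_a, inj.substituent_a), (inj.site_b, inj.substituent_b)):
        if site not in by_site:
            raise ValueError(f"injection refers to unknown site {site}")
        if name not in by_site[site]:
            raise ValueError(f"injection refers to unknown substituent {name!r} at site {site}")
    if inj.delta == 0:
        raise ValueError("injection delta must be nonzero")
    if inj.site_a == inj.site_b:
        raise ValueError("injection must couple two distinct sites")


def ground_truth_cycles(
    spec: FreeWilsonSpec,
    injections: Sequence[NAInjection] = (),
) -> list[GroundTruthCycle]:
    """Enumerate every designed DTC of the series with its exact ddpAct.

    Cycles vary substituents at two sites while all other sites are fixed.
    Interactions coupling a varied site with a fixed site cancel between the
    cycle's diagonals, so only injections on the varied site pair contribute:
    na_true = -(d(a2,b2) + d(a1,b1) - d(a1,b2) - d(a2,b1)) with c1=(a1,b1),
    c2=(a2,b1), c4=(a1,b2), c3=(a2,b2) and canonical orientation fixed by
    c1 as the double-departure corner (sign convention matches
    ``cycles.nonadditivity_value`` up to the canonical orientation chosen at
    assembly; |na_true| is orientation-free and is what tests compare).
    """
    site_ids = [s.site_id for s in spec.sites]
    subs_by_site = {s.site_id: list(s.substituents) for s in spec.sites}

    def cid(choice: dict[int, str]) -> str:
        return spec.series_id + "-" + "_".join(choice[sid] for sid in site_ids)

    def delta(choice: dict[int, str]) -> float:
        return sum(i.delta for i in injections if i.applies(choice))

    out: list[GroundTruthCycle] = []
    for si, sj in itertools.combinations(site_ids, 2):
        others = [s for s in site_ids if s not in (si, sj)]
        for a1, a2 in itertools.combinations(subs_by_site[si], 2):
            for b1, b2 in itertools.combinations(subs_by_site[sj], 2):
                for fixed in itertools.product(*[subs_by_site[s] for s in others]):
                    base = {s: sub.name for s, sub in zip(others, fixed)}
                    corners = {}
                    for tag, (a, b) in {"11": (a1, b1), "21": (a2, b1),
                                        "12": (a1, b2), "22": (a2, b2)}.items():
                        c = dict(base)
                        c[si], c[sj] = a.name, b.name
                        corners[tag] = c
                    na = -(delta(corners["22"]) + delta(corners["11"])
                           - delta(corners["12"]) - delta(corners["21"]))
                    out.append(
                        GroundTruthCycle(
                            compounds=(cid(corners["11"]), cid(corners["21"]),
                                       cid(corners["22"]), cid(corners["12"])),
                            na_true=na,
                        )
                    )
    return out


def expected_cycle_count(spec: FreeWilsonSpec) -> int:
    """Closed-form count of designed DTCs in a full combinatorial series."""
    ns = [len(s.substituents) for s in spec.sites]
    total = 0
    for i, j in itertools.combinations(range(len(ns)), 2):
        rest = 1
        for k, n in enumerate(ns):
            if k not in (i, j):
                rest *= n
        total += math.comb(ns[i], 2) * math.comb(ns[j], 2) * rest
    return total


# ---------------------------------------------------------------------------
# library builders

def default_library_spec(
    n_sites: int = 2,
    n_substituents: int = 4,
    contributions: Sequence[Sequence[float]] | None = None,
    baseline: float = 6.0,
    series_id: str = "S0",
    scaffold: str | None = None,
) -> FreeWilsonSpec:
    """A ready-made series on the default quinoline scaffolds."""
    if scaffold is None:
        if n_sites not in DEFAULT_SCAFFOLDS:
            raise ValueError(f"no default scaffold with {n_sites} sites")
        scaffold = DEFAULT_SCAFFOLDS[n_sites]
    if n_substituents > len(SUBSTITUENT_ALPHABET):
        raise ValueError("substituent alphabet exhausted")
    sites = []
    for k in range(n_sites):
        subs = []
        for m, (name, smi) in enumerate(SUBSTITUENT_ALPHABET[:n_substituents]):
            if contributions is not None:
                contrib = contributions[k][m]
            else:
                contrib = 0.3 * (m - (n_substituents - 1) / 2) * (1 if k % 2 == 0 else -1)
            subs.append(Substituent(name, smi, contrib))
        sites.append(Site(site_id=k + 1, substituents=tuple(subs)))
    return FreeWilsonSpec(scaffold=scaffold, sites=tuple(sites),
                          baseline=baseline, series_id=series_id)


_SERIES_CORES: list[str] | None = None


def _enumerate_series_cores() -> list[str]:
    """Structurally distinct 2-site biaryl scaffolds.

    Each core is a biphenyl whose rings carry varying aza substitution
    patterns; site 1 sits meta and site 2 para to the central bond.  The
    central bond is the only acyclic bond of the core, and either of its
    halves always exceeds one third of any library molecule, so the matched
    pair index can only cut at the R-group attachments: contexts from
    different cores can never collide.  Cores whose two sites become
    equivalent under symmetry are skipped.
    """
    cores: list[str] = []
    seen: set[str] = set()
    import itertools as it

    def ring1(npos: tuple[int, ...]) -> str:
        # ring atoms r1..r5 after the link atom; site 1 on r2 (meta)
        t = ["n" if k in npos else "c" for k in (1, 2, 3, 4, 5)]
        return f"{t[0]}{t[1]}([*:1]){t[2]}{t[3]}{t[4]}"

    def ring2(npos: tuple[int, ...]) -> str:
        # site 2 on r3 (para to the link)
        t = ["n" if k in npos else "c" for k in (1, 2, 3, 4, 5)]
        return f"c2{t[0]}{t[1]}{t[2]}([*:2]){t[3]}{t[4]}2"

    subsets1 = [s for n in (0, 1, 2, 3) for s in it.combinations((1, 3, 4, 5), n)]
    subsets2 = [s for n in (0, 1, 2, 3) for s in it.combinations((1, 2, 4, 5), n)]
    for s1 in subsets1:
        for s2 in subsets2:
            smi = f"c1(-{ring2(s2)}){ring1(s1)}1"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            swapped = Chem.MolToSmiles(
                Chem.MolFromSmiles(canon.replace("[*:1]", "[*:9]")
                                   .replace("[*:2]", "[*:1]")
                                   .replace("[*:9]", "[*:2]"))
            )
            # skip cores whose sites are symmetry-equivalent or already seen
            if canon == swapped or canon in seen or swapped in seen:
                continue
            seen.add(canon)
            cores.append(canon)
    return cores


def _series_core(index: int) -> str:
    """Return the ``index``-th distinct 2-site scaffold."""
    global _SERIES_CORES
    if _SERIES_CORES is None:
        _SERIES_CORES = _enumerate_series_cores()
    if index >= len(_SERIES_CORES):
        raise ValueError(f"only {len(_SERIES_CORES)} distinct series cores available")
    return _SERIES_CORES[index]


def sample_series_library(
    n_series: int,
    rng: np.random.Generator,
    n_substituents: int = 2,
    injected_fraction: float = 0.0,
    delta: float = 2.0,
    baseline_range: tuple[float, float] = (4.0, 8.5),
    contribution_scale: float = 0.5,
) -> tuple[list[LibraryMolecule], list[GroundTruthCycle]]:
    """Union of many small independent Free-Wilson series (one scaffold each).

    Emulates the sparse cycle structure of public SAR collections: each
    series is a 2-site block contributing few DTCs, so per-compound cycle
    counts stay small. ``injected_fraction`` of the series receive one
    interaction term of size ``delta`` (alternating sign) on the corner
    combining the two last substituents of their sites.
    """
    n_injected = int(round(injected_fraction * n_series))
    injected_series = set(rng.choice(n_series, size=n_injected, replace=False).tolist())
    molecules: list[LibraryMolecule] = []
    truths: list[GroundTruthCycle] = []
    for k in range(n_series):
        picks = rng.choice(len(SUBSTITUENT_ALPHABET), size=2 * n_substituents, replace=False)
        sites = []
        for s in range(2):
            subs = []
            for m in range(n_substituents):
                name, smi = SUBSTITUENT_ALPHABET[picks[s * n_substituents + m]]
                subs.append(Substituent(name, smi,
                                        float(rng.uniform(-contribution_scale,
                                                          contribution_scale))))
            sites.append(Site(site_id=s + 1, substituents=tuple(subs)))
        spec = FreeWilsonSpec(
            scaffold=_series_core(k),
            sites=tuple(sites),
            baseline=float(rng.uniform(*baseline_range)),
            series_id=f"S{k:03d}",
        )
        injections: list[NAInjection] = []
        if k in injected_series:
            sign = 1.0 if (k % 2 == 0) else -1.0
            injections.append(
                NAInjection(
                    site_a=1, substituent_a=sites[0].substituents[-1].name,
                    site_b=2, substituent_b=sites[1].substituents[-1].name,
                    delta=sign * delta,
                )
            )
        molecules.extend(enumerate_library(spec, injections))
        truths.extend(ground_truth_cycles(spec, injections))
    return molecules, truths


# ---------------------------------------------------------------------------
# curation audit fixture

def demo_curation_records(assay_id: str = "DEMO") -> list[ActivityRecord]:
    """A 40-record raw table exercising every cleaning step exactly once.

    Contents: one unparseable structure; one missing value; one "<" and one
    ">" qualified record; one negative value; one undefined unit; one
    pre-logged value; three out-of-range values (20 mM, 1 pM, 10 mM); one
    compound with replicates spanning 3.0 log units; one with three
    replicates of spread 1.0 (median survives); one structure registered
    under two ids (ethanol SMILES spelled two ways); one 71-heavy-atom
    alkane; and 22 clean single-measurement compounds. 24 unique compounds
    survive steps (2)-(7), so the minimum-size step (8) empties the assay.
    """
    A = assay_id
    py = "c1ccncc1"
    recs = [
        ActivityRecord("X1", "not_a_smiles", A, 1.0, "uM"),
        ActivityRecord("X2", py, A, None, "uM"),
        ActivityRecord("X3", py, A, 1.0, "uM", "<"),
        ActivityRecord("X4", py, A, 1.0, "uM", ">"),
        ActivityRecord("X5", py, A, -5.0, "uM"),
        ActivityRecord("X6", py, A, 1.0, "kg"),
        ActivityRecord("X7", py, A, 7.2, "logged"),
        ActivityRecord("X8", py, A, 20.0, "mM"),   # pact 1.70 < 2
        ActivityRecord("X9", py, A, 1.0, "pM"),    # pact 12 > 11
        ActivityRecord("X10", py, A, 10.0, "mM"),  # pact 2.0, open bound
        # replicate spread 3.0 > 2.5: compound removed
        ActivityRecord("CR1", "Cc1ccccc1", A, 1.0, "uM"),
        ActivityRecord("CR1", "Cc1ccccc1", A, 1.0, "nM"),
        # replicate spread 1.0: median (pact 6.4) kept
        ActivityRecord("CR2", "CCc1ccccc1", A, 1.0, "uM"),
        ActivityRecord("CR2", "CCc1ccccc1", A, 10.0 ** (-0.4), "uM"),
        ActivityRecord("CR2", "CCc1ccccc1", A, 0.1, "uM"),
        # one structure, two ids: higher-pact registration wins
        ActivityRecord("D1", "CCO", A, 1.0, "uM"),
        ActivityRecord("D2", "OCC", A, 0.5, "uM"),
        # 71 heavy atoms: over the size limit
        ActivityRecord("H1", "C" * 71, A, 1.0, "uM"),
    ]
    # 22 clean singletons (distinct alkylamines), 10 nM each
    for i in range(1, 23):
        recs.append(ActivityRecord(f"P{i:02d}", "C" * i + "N", A, 10.0, "nM"))
    assert len(recs) == 40
    return recs


# ---------------------------------------------------------------------------
# measurement emulation

@dataclass(frozen=True)
class MeasurementSpec:
    """How true pActivities become raw assay records."""

    sigma: float = 0.5
    n_replicates: int = 1
    units: tuple[str, ...] = ("uM", "nM")
    qualified_fraction: float = 0.0
    duplicate_id_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for f in (self.qualified_fraction, self.duplicate_id_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


_UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12, "fM": 1e-15}


def measure(
    library: Iterable[LibraryMolecule],
    mspec: MeasurementSpec,
    assay_id: str = "SYN",
) -> list[ActivityRecord]:
    """Emit raw ActivityRecords for a library, deterministically from the seed."""
    rng = np.random.default_rng(mspec.seed)
    records: list[ActivityRecord] = []

    def emit(cid: str, smiles: str, pact_true: float) -> None:
        for _ in range(mspec.n_replicates):
            pact_obs = pact_true + (rng.normal(0.0, mspec.sigma) if mspec.sigma > 0 else 0.0)
            unit = mspec.units[rng.integers(len(mspec.units))]
            raw = 10.0 ** (-pact_obs) / _UNIT_FACTORS[unit]
            qualifier = "<" if rng.random() < mspec.qualified_fraction else "="
            records.append(ActivityRecord(cid, smiles, assay_id, raw, unit, qualifier))

    for mol in library:
        emit(mol.compound_id, mol.smiles, mol.true_pact)
        if rng.random() < mspec.duplicate_id_fraction:
            # same structure registered under a second id with a weaker readout,
            # so curation's duplicate-structure step must drop it
            emit("dup-" + mol.compound_id, mol.smiles, mol.true_pact - 0.2)
    return records
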