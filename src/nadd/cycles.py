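"""Double-transformation cycles and the nonadditivity statistic.

A double-transformation cycle (DTC) is four compounds c1, c2, c3, c4 forming
four matched molecular pairs, linked by two transformations each applied
twice: transformation A maps c1->c2 and c4->c3, transformation B maps c1->c4
and c2->c3. Under perfectly additive SAR the two applications of A change
activity equally, so the nonadditivity

    ddpAct = (pAct2 - pAct1) - (pAct3 - pAct4)

is zero. Each of the four pActivities enters the statistic once, so with
i.i.d. per-measurement noise of standard deviation sigma the null
distribution of ddpAct is N(0, 4 sigma^2): noise impacts the statistic twice
as much as an individual measurement. Cycles are called *significant* when
|ddpAct| exceeds twice the assumed experimental uncertainty (0.6 log units
at sigma=0.3, 1.0 at sigma=0.5) and *strong* above 2.0 log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mmp import MatchedPair

STRONG_NA_THRESHOLD = 2.0


@dataclass(frozen=True)
class NoiseModel:
    """Propagated experimental-noise significance thresholds.

    sigma_exp: assumed per-measurement uncertainty in log units
        (0.3 for homogeneous in-house data, 0.5 for heterogeneous public data).
    t_significant: |ddpAct| threshold, twice sigma_exp.
    t_strong: fixed 2.0 log units.
    """

    sigma_exp: float
    t_strong: float = STRONG_NA_THRESHOLD

    @property
    def t_significant(self) -> float:
        return 2.0 * self.sigma_exp

    @property
    def null_std(self) -> float:
        """Std of ddpAct under pure noise: four errors propagate to 2 sigma."""
        return 2.0 * self.sigma_exp


@dataclass(frozen=True)
class DoubleTransformationCycle:
    compounds: tuple[str, str, str, str]          # (c1, c2, c3, c4)
    transformation_a: tuple[str, str]             # applied c1->c2 and c4->c3
    transformation_b: tuple[str, str]             # applied c1->c4 and c2->c3
    pacts: tuple[float, float, float, float]

    @property
    def nonadditivity(self) -> float:
        return nonadditivity_value(self.pacts)


def nonadditivity_value(pacts: Sequence[float]) -> float:
    """ddpAct = (pAct2 - pAct1) - (pAct3 - pAct4) for pacts (p1, p2, p3, p4)."""
    p1, p2, p3, p4 = pacts
    return (p2 - p1) - (p3 - p4)


def classify(na_value: float, noise: NoiseModel) -> str:
    """Classify |ddpAct| as 'additive', 'significant', or 'strong'."""
    a = abs(na_value)
    if a > noise.t_strong:
        return "strong"
    if a > noise.t_significant:
        return "significant"
    return "additive"


def assemble_cycles(
    pairs: Iterable[MatchedPair],
    pacts: Mapping[str, float],
) -> list[DoubleTransformationCycle]:
    """Assemble all DTCs supported by a matched-pair list.

    Every quadruple whose four edges exist with matching transformations is
    emitted exactly once in canonical orientation: transformation A is the
    lexicographically smaller of the two transformation keys, both
    transformations depart (in their canonical direction) from c1, and for
    symmetric cases the orientation with the smaller c2 id is kept.
    """
    # directed edges per transformation key, plus transformation lookup per edge
    edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    ts_of: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for p in pairs:
        t = p.transformation
        e = (p.compound_from, p.compound_to)
        labels = ts_of.setdefault(e, set())
        if t not in labels:
            labels.add(t)
            edges.setdefault(t, []).append(e)

    seen: set[tuple] = set()
    out: list[DoubleTransformationCycle] = []
    for t_a in sorted(edges):
        edge_list = edges[t_a]
        for u1, v1 in edge_list:
            for u2, v2 in edge_list:
                if u1 == u2:  # includes identical edges
                    continue
                if len({u1, v1, u2, v2}) != 4:
                    continue
                t_bs = ts_of.get((u1, u2), set()) & ts_of.get((v1, v2), set())
                for t_b in t_bs:
                    c1, c2, c3, c4 = u1, v1, v2, u2
                    if t_b < t_a:
                        # make the smaller transformation play role A
                        ta, tb = t_b, t_a
                        c2, c4 = c4, c2
                    else:
                        ta, tb = t_a, t_b
                    if ta == tb and c4 < c2:
                        c2, c4 = c4, c2
                    key = (ta, tb, c1, c2, c3, c4)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        DoubleTransformationCycle(
                            compounds=(c1, c2, c3, c4),
                            transformation_a=ta,
                            transformation_b=tb,
                            pacts=(pacts[c1], pacts[c2], pacts[c3], pacts[c4]),
                        )
                    )
    out.sort(key=lambda c: (c.transformation_a, c.transformation_b, c.compounds))
    return out


def theoretical_noise_density(sigma_exp: float, grid: np.ndarray) -> np.ndarray:
    """Null density of ddpAct under pure experimental noise: N(0, (2 sigma)^2)."""
    if sigma_exp <= 0:
        raise ValueError("sigma_exp must be positive")
    return stats.norm.pdf(grid, loc=0.0, scale=2.0 * sigma_exp)


def simulate_noise_cycles(
    n_cycles: int, sigma_exp: float, rng: np.random.Generator
) -> np.ndarray:
    """ddpAct values of cycles whose four pActivities are pure noise draws."""
    p = rng.normal(0.0, sigma_exp, size=(n_cycles, 4))
    return (p[:, 1] - p[:, 0]) - (p[:, 2] - p[:, 3])


# ---------------------------------------------------------------------------
# per-compound profiles

@dataclass
class CompoundNAProfile:
    """Additivity shift summary for one compound across its cycles.

    ``mean_shift`` averages the compound's signed shifts, each computed with
    the compound oriented at the doubly-transformed corner c3 and signed as
    observed-minus-additive-expectation: shift = (p_focal + p_opposite) -
    (p_adjacent1 + p_adjacent2). A compound whose activity is boosted by
    delta beyond additivity shows mean shift +delta. The 95% null band is
    +/- 1.96 * 2 sigma_exp / sqrt(n_cycles).
    """

    compound_id: str
    n_cycles: int
    mean_shift: float
    std_shift: float
    ci_low: float
    ci_high: float
    significant: bool
    na_values: list[float] = field(default_factory=list)

    @property
    def na_max_abs(self) -> float:
        return max(abs(v) for v in self.na_values)

    @property
    def na_mean_abs(self) -> float:
        return sum(abs(v) for v in self.na_values) / len(self.na_values)


def _member_shifts(cycle: DoubleTransformationCycle) -> dict[str, float]:
    """Signed additivity shift contributed by one cycle to each member."""
    c1, c2, c3, c4 = cycle.compounds
    p1, p2, p3, p4 = cycle.pacts
    na = (p2 - p1) - (p3 - p4)
    # c1 and c3 sit on the negative diagonal of the statistic, c2 and c4 on
    # the positive one; re-orienting the focal compound to c3 and flipping to
    # observed-minus-expected gives -na for the (c2, c4) diagonal and +...:
    # shift_f = p_f + p_opp - p_adj1 - p_adj2
    d13 = (p1 + p3) - (p2 + p4)   # = -na
    d24 = (p2 + p4) - (p1 + p3)   # = +na
    return {c1: d13, c3: d13, c2: d24, c4: d24}


def compound_profiles(
    cycles: Sequence[DoubleTransformationCycle],
    noise: NoiseModel,
    significance_rule: str = "any_cycle",
) -> list[CompoundNAProfile]:
    """Per-compound occurrence counts, mean/std shift and significance flag.

    significance_rule:
        "any_cycle" (default) — flag a compound if any of its cycles has
            |ddpAct| above ``noise.t_significant``;
        "mean_outside_ci" — flag if |mean shift| falls outside the 95% null
            band for its cycle count.
    """
    if significance_rule not in ("any_cycle", "mean_outside_ci"):
        raise ValueError(f"unknown significance rule {significance_rule!r}")
    shifts: dict[str, list[float]] = {}
    nas: dict[str, list[float]] = {}
    for cyc in cycles:
        na = cyc.nonadditivity
        for cid, s in _member_shifts(cyc).items():
            shifts.setdefault(cid, []).append(s)
            nas.setdefault(cid, []).append(na)
    out = []
    for cid in sorted(shifts):
        vals = np.asarray(shifts[cid])
        n = len(vals)
        half = 1.96 * noise.null_std / math.sqrt(n)
        mean = float(vals.mean())
        if significance_rule == "any_cycle":
            sig = any(abs(v) > noise.t_significant for v in nas[cid])
        else:
            sig = abs(mean) > half
        out.append(
            CompoundNAProfile(
                compound_id=cid,
                n_cycles=n,
                mean_shift=mean,
                std_shift=float(vals.std(ddof=1)) if n > 1 else 0.0,
                ci_low=-half,
                ci_high=half,
                significant=sig,
                na_values=nas[cid],
            )
        )
    return out


# ---------------------------------------------------------------------------
# assay-level summary

@dataclass
class AssayNASummary:
    assay_id: str
    n_compounds: int
    n_compounds_in_cycles: int
    n_cycles: int
    n_cycles_significant: int
    n_cycles_strong: int
    n_compounds_significant: int
    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis_excess: float
    normality_p: float

    @property
    def frac_cycles_significant(self) -> float:
        return self.n_cycles_significant / self.n_cycles if self.n_cycles else 0.0

    @property
    def frac_cycles_strong(self) -> float:
        return self.n_cycles_strong / self.n_cycles if self.n_cycles else 0.0


def assay_summary(
    assay_id: str,
    cycles: Sequence[DoubleTransformationCycle],
    n_compounds: int,
    noise: NoiseModel,
    profiles: Sequence[CompoundNAProfile] | None = None,
) -> AssayNASummary:
    """Counts, classification tallies and moment statistics for one assay.

    Kurtosis is reported as excess kurtosis (normal reference = 0). The
    normality p-value is a Kolmogorov–Smirnov test of the signed ddpAct
    sample against N(0, sample std) — the sample std is plugged in, so the
    p-value is approximate.
    """
    if profiles is None:
        profiles = compound_profiles(cycles, noise)
    na = np.asarray([c.nonadditivity for c in cycles])
    n_sig = int(np.sum(np.abs(na) > noise.t_significant)) if len(na) else 0
    n_strong = int(np.sum(np.abs(na) > noise.t_strong)) if len(na) else 0
    if len(na) >= 2 and float(na.std(ddof=0)) > 0:
        ks = stats.kstest(na, "norm", args=(0.0, float(na.std(ddof=1))))
        normality_p = float(ks.pvalue)
    else:
        normality_p = float("nan")
    return AssayNASummary(
        assay_id=assay_id,
        n_compounds=n_compounds,
        n_compounds_in_cycles=len({c for cyc in cycles for c in cyc.compounds}),
        n_cycles=len(na),
        n_cycles_significant=n_sig,
        n_cycles_strong=n_strong,
        n_compounds_significant=sum(p.significant for p in profiles),
        mean=float(na.mean()) if len(na) else float("nan"),
        variance=float(na.var(ddof=1)) if len(na) > 1 else float("nan"),
        std=float(na.std(ddof=1)) if len(na) > 1 else float("nan"),
        skewness=float(stats.skew(na)) if len(na) > 2 else float("nan"),
        kurtosis_excess=float(stats.kurtosis(na, fisher=True)) if len(na) > 3 else float("nan"),
        normality_p=normality_p,
    )


def compare_distributions(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Rank-based comparison of two signed ddpAct samples.

    Returns (Kruskal–Wallis p, two-sided Mann–Whitney U p). Degenerate
    all-tied inputs yield (nan, nan).
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float("nan"), float("nan")
    kw = stats.kruskal(a, b)
    mw = stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=False)
    return float(kw.pvalue), float(mw.pvalue)


# ---------------------------------------------------------------------------
# tabular output

def cycles_to_frame(cycles: Sequence[DoubleTransformationCycle]) -> pd.DataFrame:
    rows = []
    for c in cycles:
        rows.append(
            c.compounds
            + (f"{c.transformation_a[0]}>>{c.transformation_a[1]}",
               f"{c.transformation_b[0]}>>{c.transformation_b[1]}")
            + c.pacts
            + (c.nonadditivity,)
        )
    return pd.DataFrame(
        rows,
        columns=["c1", "c2", "c3", "c4", "transformation_a", "transformation_b",
                 "pact_1", "pact_2", "pact_3", "pact_4", "nonadditivity"],
    )


def profiles_to_frame(
    profiles: Sequence[CompoundNAProfile],
    smiles: Mapping[str, str] | None = None,
    pacts: Mapping[str, float] | None = None,
    all_compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Supplementary-style per-compound table.

    One row per compound: id, SMILES, pActivity, number of DTC occurrences,
    and both candidate per-compound absolute NA aggregates (max and mean over
    its cycles). Compounds in no cycle get empty occurrence/NA fields.
    """
    by_id = {p.compound_id: p for p in profiles}
    ids = list(all_compounds) if all_compounds is not None else sorted(by_id)
    rows = []
    for cid in ids:
        p = by_id.get(cid)
        rows.append({
            "compound_id": cid,
            "smiles": smiles.get(cid, "") if smiles else "",
            "pact": pacts.get(cid, float("nan")) if pacts else float("nan"),
            "n_cycles": p.n_cycles if p else pd.NA,
            "na_max_abs": p.na_max_abs if p else pd.NA,
            "na_mean_abs": p.na_mean_abs if p else pd.NA,
            "mean_shift": p.mean_shift if p else pd.NA,
            "std_shift": p.std_shift if p else pd.NA,
            "ci_low": p.ci_low if p else pd.NA,
            "ci_high": p.ci_high if p else pd.NA,
            "significant": p.significant if p else False,
        })
    return pd.DataFrame(rows)
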