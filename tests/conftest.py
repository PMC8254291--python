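import numpy as np
import pytest

from nadd import simulate


@pytest.fixture(scope="session")
def block_2x2():
    """Minimal 2-site x 2-substituent Free-Wilson block (exactly one cycle)."""
    return simulate.default_library_spec(n_sites=2, n_substituents=2)


@pytest.fixture(scope="session")
def block_2x3():
    spec = simulate.FreeWilsonSpec(
        scaffold=simulate.DEFAULT_SCAFFOLDS[2],
        sites=(
            simulate.Site(1, (simulate.Substituent("methyl", "C", 0.2),
                              simulate.Substituent("ethyl", "CC", -0.1))),
            simulate.Site(2, (simulate.Substituent("chloro", "Cl", 0.5),
                              simulate.Substituent("fluoro", "F", 0.0),
                              simulate.Substituent("methoxy", "OC", -0.4))),
        ),
        baseline=6.5,
    )
    return spec


@pytest.fixture(scope="session")
def study_assay():
    """The reference synthetic study assay (shared; expensive to build)."""
    from nadd import study

    return study.build_study_assay(seed=7)


def brute_force_cycles(pairs):
    """Independent DTC oracle: exhaustive quadruple enumeration over a pair list.

    Returns the set of canonical cycle keys (tA, tB, c1, c2, c3, c4):
    transformation A lexicographically smallest, both transformations leaving
    c1 in their canonical (stored) direction, c2 < c4 when A == B.
    """
    t_of = {}
    compounds = set()
    for p in pairs:
        t_of.setdefault((p.compound_from, p.compound_to), set()).add(p.transformation)
        compounds.update((p.compound_from, p.compound_to))
    compounds = sorted(compounds)
    found = set()
    for c1 in compounds:
        for c2 in compounds:
            for c3 in compounds:
                for c4 in compounds:
                    if len({c1, c2, c3, c4}) != 4:
                        continue
                    tas = t_of.get((c1, c2), set()) & t_of.get((c4, c3), set())
                    if not tas:
                        continue
                    tbs = t_of.get((c1, c4), set()) & t_of.get((c2, c3), set())
                    for ta in tas:
                        for tb in tbs:
                            a, b = ta, tb
                            x2, x4 = c2, c4
                            if b < a:
                                a, b = b, a
                                x2, x4 = x4, x2
                            if a == b and x4 < x2:
                                x2, x4 = x4, x2
                            found.add((a, b, c1, x2, c3, x4))
    return found


def random_toy_library(rng: np.random.Generator):
    """A small randomized Free-Wilson library (<= 30 compounds) for oracles."""
    n_sites = int(rng.integers(2, 4))
    if n_sites == 3:
        counts = [2, 2, 2]
    else:
        counts = [int(rng.integers(2, 5)), int(rng.integers(2, 5))]
    picks = rng.choice(len(simulate.SUBSTITUENT_ALPHABET), size=sum(counts),
                       replace=False)
    sites, k = [], 0
    for s, n in enumerate(counts):
        subs = []
        for _ in range(n):
            name, smi = simulate.SUBSTITUENT_ALPHABET[picks[k]]
            subs.append(simulate.Substituent(name, smi, float(rng.normal(0, 0.4))))
            k += 1
        sites.append(simulate.Site(s + 1, tuple(subs)))
    spec = simulate.FreeWilsonSpec(
        scaffold=simulate.DEFAULT_SCAFFOLDS[n_sites],
        sites=tuple(sites),
        baseline=float(rng.uniform(5, 8)),
    )
    mols = simulate.enumerate_library(spec)
    keep = [m for m in mols if rng.random() > 0.25]
    return keep if len(keep) >= 4 else mols
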