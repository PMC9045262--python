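import numpy as np
import pytest

import sdpmark as sm


@pytest.fixture
def three_genome_chain() -> sm.AniMatrix:
    """A-B 96, B-C 96, A-C 90: one component at 95, three at 99.9."""
    vals = np.array(
        [[100.0, 96.0, 90.0], [96.0, 100.0, 96.0], [90.0, 96.0, 100.0]]
    )
    return sm.AniMatrix(["A", "B", "C"], vals)


@pytest.fixture
def small_family():
    """A 5-SDP simulated gene family with conserved flanks (seeded)."""
    spec = sm.SimSpec(seed=11)
    return sm.simulate_gene_family(spec)


def random_ani(rng: np.random.Generator, n: int) -> sm.AniMatrix:
    vals = rng.uniform(70, 100, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 100.0)
    return sm.AniMatrix([f"g{i:02d}" for i in range(n)], vals)


def brute_force_components(ani: sm.AniMatrix, threshold: float):
    """Oracle: transitive closure by repeated merging of member sets."""
    groups = [{g} for g in ani.ids]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                linked = any(
                    ani.pair(a, b) >= threshold for a in groups[i] for b in groups[j]
                )
                if linked:
                    groups[i] |= groups.pop(j)
                    changed = True
                    break
            if changed:
                break
    return frozenset(frozenset(g) for g in groups)
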