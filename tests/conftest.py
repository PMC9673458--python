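import numpy as np
import pytest

from plfcm import LinguisticScale, PLTS, SyntheticSpec, generate_synthetic


@pytest.fixture
def state_scale():
    return LinguisticScale(5)


@pytest.fixture
def weight_scale():
    return LinguisticScale(3)


def random_plts(rng, scale, max_len=4, normalized=True):
    """Random integer-term PLTS on the given scale."""
    k = int(rng.integers(1, max_len + 1))
    terms = rng.choice(np.arange(-scale.tau, scale.tau + 1), size=k, replace=False)
    probs = rng.dirichlet(np.ones(k))
    if not normalized:
        probs = probs * rng.uniform(0.3, 1.0)
    return PLTS(tuple(sorted(zip(terms.tolist(), probs.tolist()))), scale)


@pytest.fixture
def make_random_plts():
    return random_plts


@pytest.fixture
def converging_model():
    """A seeded synthetic map that reaches a fixed point under defaults."""
    return generate_synthetic(SyntheticSpec(n_nodes=8, edge_density=0.4, seed=7))


def naive_step(h, p, adj, wm, wp, lam=1.0, squash=None):
    """Per-node, per-position double-loop oracle for one engine step."""
    n, l = h.shape
    h_next = np.empty_like(h)
    p_next = np.empty_like(p)
    for i in range(n):
        for k in range(l):
            prod_m = 1.0
            prod_p = 1.0
            for j in range(n):
                if j != i and adj[j, i]:
                    prod_m *= 1.0 - h[j, k] * wm[j, i, k]
                    prod_p *= 1.0 - p[j, k] * wp[j, i, k]
            a = 1.0 - prod_m
            b = 1.0 - prod_p
            xm = h[i, k] + a - h[i, k] * a
            xp = p[i, k] + b - p[i, k] * b
            if squash is None:
                h_next[i, k] = np.tanh(lam * xm)
                p_next[i, k] = np.tanh(lam * xp)
            else:
                h_next[i, k] = squash(xm, lam)
                p_next[i, k] = squash(xp, lam)
    for i in range(n):
        p_next[i] /= p_next[i].sum()
    return h_next, p_next
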