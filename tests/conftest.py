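import numpy as np
import pytest

from gramrsa.design import CORE_MODELS, build_condition_set, build_model

#: master seed for every seeded test in the suite
SEED = 20260927


@pytest.fixture(scope="session")
def cs():
    return build_condition_set()


@pytest.fixture(scope="session")
def models(cs):
    return {name: build_model(name, cs) for name in CORE_MODELS}


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


# ---------------------------------------------------------------------------
# independent brute-force oracles (textbook formulas, pure python)


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def midranks_oracle(v):
    order = sorted(range(len(v)), key=lambda k: v[k])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(midranks_oracle(list(x)), midranks_oracle(list(y)))


def tau_a_oracle(x, y):
    n = len(x)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2.0)
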