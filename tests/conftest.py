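"""Shared fixtures and the independent brute-force energy oracle."""

import math

import numpy as np
import pytest

from mtorpot import (
    InternalGeometry,
    MtorParamSet,
    PAIRS,
    ReducedSequence,
    bundled_param_set,
)


def brute_force_chain_energy(theta_deg, gamma_deg, types, params):
    """Naive triple-loop (M, m, i) evaluation, translated 1-based from the
    defining product formula.  Deliberately independent of the package's
    vectorized implementation."""
    n = len(types)
    th = [math.radians(t) for t in theta_deg]
    ga = [math.radians(g) for g in gamma_deg]

    def T(k):      # 1-based virtual-bond angle with vertex at residue k
        return th[k - 2]

    def G(k):      # 1-based dihedral with axis on the k..k+1 bond
        return ga[k - 2]

    def PSI(k):    # phase of the ordered pair flanking that axis bond
        return math.radians(params.psi_deg[types[k - 1] + types[k]])

    total = 0.0
    for M, w in sorted(params.weights.items()):
        if w == 0.0:
            continue
        for m in range(7, min(params.m_max, n) + 1):
            for i in range(1, n - m + 2):
                t = math.sin(T(i + 1)) ** M * math.sin(M * (G(i + 1) + PSI(i + 1)))
                for k in range(i + 2, i + m - 3):
                    t *= math.sin(T(k)) ** (2 * M) * math.cos(M * (G(k) + PSI(k)))
                t *= math.sin(T(i + m - 3)) ** (2 * M) * math.sin(M * (G(i + m - 3) + PSI(i + m - 3)))
                t *= math.sin(T(i + m - 2)) ** M
                total -= w * t
    return total


def ideal_fragment(n, theta=90.0, gamma=45.0, types=None):
    """InternalGeometry + ReducedSequence of an idealized helical fragment."""
    geom = InternalGeometry(n=n, theta=np.full(n - 2, float(theta)),
                            gamma=np.full(n - 3, float(gamma)))
    seq = ReducedSequence(types if types is not None else "A" * n)
    return geom, seq


@pytest.fixture
def oracle():
    return brute_force_chain_energy


@pytest.fixture
def zero_psi():
    """Unit-weight M=1 set with all phase angles zero: hand-checkable."""
    return MtorParamSet(weights={1: 1.0, 2: 0.0}, psi_deg=dict.fromkeys(PAIRS, 0.0))


@pytest.fixture(params=["A", "B", "C"])
def bundled_set(request):
    return bundled_param_set(request.param)


@pytest.fixture
def set_b():
    return bundled_param_set("B")


def random_fragment(rng, n, types=None):
    """Random internal coordinates of an n-residue fragment (all defined)."""
    theta = rng.uniform(20.0, 160.0, n - 2)
    gamma = rng.uniform(0.0, 360.0, n - 3)
    types = types if types is not None else "".join(rng.choice(list("GAP"), n))
    return InternalGeometry(n=n, theta=theta, gamma=gamma), ReducedSequence(types)
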