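"""Shared fixtures and independent oracles for the test suite.

The heavyweight oracle here is a finite-state-projection (FSP) solver: the
stationary distribution of the full chemical master equation on a truncated
(s, m, p) lattice, solved as a sparse linear system.  For low-count rate
sets the truncation error is driven below 1e-12, giving ground-truth joint
moments that are independent of the package's moment-equation assembly.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import spsolve

from acesfit.model import CDRCRanges, CDRCSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


def random_cdrc(rng, k_off_zero=False) -> CDRCSet:
    """A moderate, well-conditioned random rate set (log-uniform draws)."""
    draw = lambda lo, hi: 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    return CDRCSet(
        k_on=draw(0.05, 5.0),
        k_off=0.0 if k_off_zero else draw(0.05, 5.0),
        k_r=draw(0.2, 20.0),
        k_p=draw(0.1, 10.0),
        g_r=draw(0.2, 5.0),
        g_p=draw(0.01, 0.5),
    )


@pytest.fixture(scope="session")
def two_decade_ranges() -> CDRCRanges:
    """Narrowed search box: two decades per rate around moderate values."""
    return CDRCRanges(
        k_on=(0.05, 5.0),
        k_off=(0.05, 5.0),
        k_r=(0.5, 50.0),
        k_p=(0.1, 10.0),
        g_r=(0.1, 10.0),
        g_p=(0.005, 0.5),
    )


class FSP:
    """Dense stationary CME solution on the truncated lattice m<=mmax, p<=pmax."""

    def __init__(self, cdrc: CDRCSet, mmax: int, pmax: int):
        k_on, k_off, k_r, k_p, g_r, g_p = cdrc.as_tuple()
        self.mmax, self.pmax = mmax, pmax
        nm, npp = mmax + 1, pmax + 1
        n = 2 * nm * npp

        def idx(s, m, p):
            return (s * nm + m) * npp + p

        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for s in range(2):
            for m in range(nm):
                for p in range(npp):
                    i = idx(s, m, p)
                    out = 0.0
                    if s == 0:
                        add(idx(1, m, p), i, k_on)
                        out += k_on
                    else:
                        add(idx(0, m, p), i, k_off)
                        out += k_off
                    if s == 1 and m < mmax:
                        add(idx(s, m + 1, p), i, k_r)
                        out += k_r
                    if m > 0:
                        add(idx(s, m - 1, p), i, g_r * m)
                        out += g_r * m
                    if p < pmax:
                        add(idx(s, m, p + 1), i, k_p * m)
                        out += k_p * m
                    if p > 0:
                        add(idx(s, m, p - 1), i, g_p * p)
                        out += g_p * p
                    add(i, i, -out)
        self.generator = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        A = self.generator.tolil()
        A[0, :] = 1.0
        b = np.zeros(n)
        b[0] = 1.0
        self.pi = spsolve(A.tocsr(), b)
        self.S = np.arange(2).repeat(nm * npp)
        self.M = np.tile(np.arange(nm).repeat(npp), 2)
        self.P = np.tile(np.arange(npp), 2 * nm)

    @property
    def boundary_mass(self) -> float:
        edge = (self.M == self.mmax) | (self.P == self.pmax)
        return float(self.pi[edge].sum())

    def raw_moment(self, a: int, i: int, j: int) -> float:
        return float(np.sum(self.pi * self.S**a * self.M.astype(float) ** i * self.P.astype(float) ** j))

    def protein_central_moments(self) -> tuple[float, float, float, float]:
        mean = self.raw_moment(0, 0, 1)

        def cm(k):
            return float(np.sum(self.pi * (self.P - mean) ** k))

        return mean, cm(2), cm(3), cm(4)
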