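"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: digestion
is re-derived by enumerating substrings, the hypergeometric tail by exact
combinatorial summation, and Gaussian peak areas from the closed form.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mitoredox.model import CysteineSite, TruthRecord


# ---------------------------------------------------------------------------
# oracles


def brute_force_digest(
    sequence: str, max_missed: int, min_len: int, max_len: int
) -> list[tuple[str, int, int]]:
    """Enumerate every substring whose boundaries are valid tryptic cut
    points and whose internal missed-cleavage count is within budget.

    Returns (peptide, 1-based start, missed cleavages) sorted by start
    then length.
    """
    cut_after = {
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    }
    starts = {0} | {i + 1 for i in cut_after}
    ends = {i + 1 for i in cut_after} | {len(sequence)}
    out = []
    for s in starts:
        for e in ends:
            if e <= s or not (min_len <= e - s <= max_len):
                continue
            internal = sum(1 for i in cut_after if s <= i < e - 1)
            if internal <= max_missed:
                out.append((sequence[s:e], s + 1, internal))
    out.sort(key=lambda t: (t[1], len(t[0])))
    return out


def brute_force_hypergeom_tail(M: int, K: int, N: int, k: int) -> float:
    """P(overlap >= k) drawing N from M with K marked, by exact summation."""
    total = math.comb(M, N)
    return sum(
        math.comb(K, i) * math.comb(M - K, N - i)
        for i in range(k, min(K, N) + 1)
    ) / total


def gaussian_area(height: float, sigma: float) -> float:
    return height * sigma * math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# fixtures


def make_site(protein_id: str = "P0001", residue: int = 10, peptide: str = "ACK") -> CysteineSite:
    return CysteineSite(protein_id=protein_id, residue=residue, peptide=peptide)


def make_truth(
    site: CysteineSite | None = None,
    fmax_rev: float = 0.8,
    K: float = 2.5,
    hill: float = 1.0,
    firr_frac: float = 0.0,
    detect_isotop: float = 1.0,
    detect_oxicat: float = 1.0,
    basal_ox: float = 0.0,
    sensitivity_class: str = "moderate",
) -> TruthRecord:
    return TruthRecord(
        site=site or make_site(),
        fmax_rev=fmax_rev,
        K=K,
        hill=hill,
        firr_frac=firr_frac,
        detect_isotop=detect_isotop,
        detect_oxicat=detect_oxicat,
        basal_ox=basal_ox,
        sensitivity_class=sensitivity_class,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_proteome() -> dict[str, str]:
    from mitoredox.synthetic_data import random_proteome

    return random_proteome(8, (80, 160), seed=7)


@pytest.fixture
def toy_sites(toy_proteome):
    from mitoredox.synthetic_data import build_sites

    return build_sites(toy_proteome)
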