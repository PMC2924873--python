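import itertools
from fractions import Fraction

import networkx as nx
import pytest
import sympy

from mirenrich.builder import GenomicLocus
from mirenrich.fixtures import ami_fixture


# ---------------------------------------------------------------------------
# Independent oracles.  These deliberately avoid the package's own code
# paths: sympy rationals instead of math.comb/Fraction, full subset
# enumeration at tiny population sizes, and networkx for cluster graphs.
# ---------------------------------------------------------------------------

def oracle_pmf(P: int, HP: int, S: int, HS: int) -> Fraction:
    """Exact hypergeometric mass via sympy binomials."""
    num = sympy.binomial(HP, HS) * sympy.binomial(P - HP, S - HS)
    den = sympy.binomial(P, S)
    return Fraction(int(num), int(den))


def oracle_p_over(P: int, HP: int, S: int, HS: int) -> Fraction:
    return sum((oracle_pmf(P, HP, S, h) for h in range(HS, S + 1)), Fraction(0))


def oracle_p_under(P: int, HP: int, S: int, HS: int) -> Fraction:
    return sum((oracle_pmf(P, HP, S, h) for h in range(0, HS + 1)), Fraction(0))


def enumeration_pmf(P: int, HP: int, S: int, HS: int) -> Fraction:
    """Brute-force mass by enumerating every S-subset of a P-element urn.

    Only feasible for tiny P; the ground truth against which the
    rational oracle itself is sanity-checked.
    """
    marked = set(range(HP))
    total = hits = 0
    for subset in itertools.combinations(range(P), S):
        total += 1
        if len(marked.intersection(subset)) == HS:
            hits += 1
    return Fraction(hits, total)


def oracle_clusters(loci, max_gap, same_strand=False):
    """All-pairs gap graph + networkx connected components."""
    g = nx.Graph()
    for loc in loci:
        g.add_node((loc.mirna, loc.chrom, loc.start))
    for a, b in itertools.combinations(loci, 2):
        if a.chrom != b.chrom:
            continue
        if same_strand and a.strand != b.strand:
            continue
        left, right = (a, b) if a.start <= b.start else (b, a)
        gap = max(0, right.start - left.end - 1)
        if gap <= max_gap:
            g.add_edge((a.mirna, a.chrom, a.start), (b.mirna, b.chrom, b.start))
    partitions = []
    for comp in nx.connected_components(g):
        members = frozenset(n[0] for n in comp)
        if len(members) >= 2:
            partitions.append(members)
    return set(partitions)


def oracle_bh(pvals):
    """Naive O(m^2) Benjamini-Hochberg step-up."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank, i in enumerate(order, start=1):
        candidates = []
        for rank2, j in enumerate(order, start=1):
            if rank2 >= rank:
                candidates.append(pvals[j] * m / rank2)
        q[i] = min(1.0, min(candidates))
    return q


def oracle_bonferroni(pvals):
    return [min(1.0, p * len(pvals)) for p in pvals]


def valid_count_tuples(max_P):
    """Every valid (P, HP, S, HS) with 1 <= P <= max_P."""
    for P in range(1, max_P + 1):
        for HP in range(0, P + 1):
            for S in range(0, P + 1):
                for HS in range(0, min(S, HP) + 1):
                    yield P, HP, S, HS


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ami():
    return ami_fixture()


@pytest.fixture
def three_loci():
    """The canonical chaining example: 2 near genes, 1 far."""
    return [
        GenomicLocus("mir-a", "chr1", 1000, 1100, "+"),
        GenomicLocus("mir-b", "chr1", 45000, 45100, "+"),
        GenomicLocus("mir-c", "chr1", 120000, 120100, "+"),
    ]
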