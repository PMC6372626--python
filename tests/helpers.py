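"""Independent oracles shared by the unit and acceptance suites.

Everything here is deliberately written without reusing package code
paths: brute-force tail summation, a textbook step-up BH, and a literal
decision-table mechanism classifier.
"""

from math import comb

import numpy as np


def binom_tail_bruteforce(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by exhaustive pmf summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for x in range(k, n + 1):
        total += comb(n, x) * (p ** x) * ((1 - p) ** (n - x))
    return min(total, 1.0)


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg adjusted values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def mechanism_decision_table(sv_type, homology_code, n_junctions, te_hit, vntr_hit):
    """Literal restatement of the mechanism rules as a flat decision table."""
    if sv_type == "TEI":
        return "TEI"
    if sv_type == "insertion" and te_hit:
        return "TEI"
    if sv_type == "VNTR":
        return "VNTR"
    if vntr_hit:
        return "VNTR"
    if n_junctions > 2:
        return "FoSTeS/MMBIR"
    if homology_code in (0, 1, 2):
        return "NHEJ"
    if -10 <= homology_code <= -1:
        return "NHEJ"
    if 3 <= homology_code <= 100:
        return "alt-EJ"
    return "unclassified"


def expected_subtype(n_sv, max_fraction):
    """Literal restatement of the published burden rules, in rule order."""
    if n_sv < 50:
        return "stable"
    if max_fraction > 0.25:
        return "locally_rearranged"
    if n_sv > 200:
        return "unstable"
    return "scattered"
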