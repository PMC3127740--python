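"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mirasym.duplex_structure import ScoreModel

# Worked-example sequences (pre-miR-2a-1 hairpin and its two mature strands)
MIR2A_HAIRPIN = "UCUCAAAGUGGUUGUGAAAUGCAUUUCCGCUUUGCGCGGCAUAUCACAGCCAGCUUUGAUGAGC"
MIR2A = "UAUCACAGCCAGCUUUGAUGAGC"  # 3p arm strand, 23 nt
MIR2A_STAR = "UCUCAAAGUGGUUGUGAAAUG"  # 5p arm strand, 21 nt


def brute_force_pair_probs(seq_a: str, seq_b: str, model: ScoreModel) -> np.ndarray:
    """Exhaustive enumeration of all non-crossing intermolecular pairings.

    Independent of the DP engine: generates every monotone chain of
    complementary (i, j) pairs, scores it with the same documented additive
    score, and accumulates Boltzmann-weighted pair frequencies.
    """
    na, nb = len(seq_a), len(seq_b)
    pairs = [
        (i, j)
        for i in range(1, na + 1)
        for j in range(1, nb + 1)
        if model.pair_score(seq_a[i - 1], seq_b[j - 1]) is not None
    ]
    order = sorted(pairs, key=lambda x: (x[0], -x[1]))
    P = np.zeros((na, nb))
    Z = 0.0

    def chains(chosen, rest):
        yield chosen
        for k, (i, j) in enumerate(rest):
            if not chosen or (i > chosen[-1][0] and j < chosen[-1][1]):
                yield from chains(chosen + [(i, j)], rest[k + 1 :])

    for chain in chains([], order):
        score = sum(model.pair_score(seq_a[i - 1], seq_b[j - 1]) for i, j in chain)
        for m in range(len(chain) - 1):
            (i1, j1), (i2, j2) = chain[m], chain[m + 1]
            score += model.loop_score(i2 - i1 - 1, j1 - j2 - 1)
        w = np.exp(score)
        Z += w
        for i, j in chain:
            P[i - 1, j - 1] += w
    return P / Z


def fixed_margin_tables(row_sums, col_sums):
    """All non-negative integer tables with the given margins (oracle)."""
    r, c = len(row_sums), len(col_sums)
    out = []

    def rows(row_idx, remaining, acc):
        if row_idx == r - 1:
            if all(v >= 0 for v in remaining):
                out.append(np.array(acc + [list(remaining)]))
            return
        for row in compositions(row_sums[row_idx], remaining):
            rows(row_idx + 1, [remaining[k] - row[k] for k in range(c)], acc + [row])

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield [total]
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in compositions(total - v, caps[1:]):
                yield [v] + rest

    rows(0, list(col_sums), [])
    return out


def log_table_prob(table: np.ndarray) -> float:
    """Fixed-margins hypergeometric log probability (oracle arithmetic)."""
    from math import lgamma

    table = np.asarray(table)
    n = table.sum()
    lp = -lgamma(n + 1)
    for rs in table.sum(axis=1):
        lp += lgamma(rs + 1)
    for cs in table.sum(axis=0):
        lp += lgamma(cs + 1)
    for v in table.ravel():
        lp -= lgamma(v + 1)
    return lp


def fisher_exact_oracle(table) -> float:
    """Two-sided exact p by full enumeration of the margin-fixed table space."""
    table = np.asarray(table, dtype=int)
    lp_obs = log_table_prob(table)
    p = 0.0
    for t in fixed_margin_tables(list(table.sum(axis=1)), list(table.sum(axis=0))):
        lp = log_table_prob(t)
        if lp <= lp_obs + 1e-9 * abs(lp_obs):
            p += np.exp(lp)
    return min(p, 1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    from mirasym import SyntheticParams, generate_cohort

    params = SyntheticParams(
        n_hairpins=40,
        seed=42,
        isoform_jitter=0.1,
        mirna_nt1_probs=(0.07, 0.07, 0.07, 0.79),
        star_nt1_probs=(0.3, 0.25, 0.3, 0.15),
    )
    return generate_cohort(params)
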