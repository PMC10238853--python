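"""Shared test oracles."""

from scipy import stats


def exact_5plus2_distribution(pc1, pp1, pc2, pp2):
    """Exact outcome probabilities of the 5+2 design by enumerating the
    finite outcome tree with independent per-patient Bernoulli endpoints.

    Returns dict with keys 'infeasible', 'mtd1', 'mtd2', 'mean_n'.
    """
    b5c = [stats.binom.pmf(k, 5, pc1) for k in range(6)]
    b5p = [stats.binom.pmf(k, 5, pp1) for k in range(6)]
    b2c = [stats.binom.pmf(k, 2, pc1) for k in range(3)]
    b2p = [stats.binom.pmf(k, 2, pp1) for k in range(3)]

    p_infeasible_5 = 0.0
    p_infeasible_7 = 0.0
    p_cohort2_n12 = 0.0
    p_cohort2_n14 = 0.0
    for c5 in range(6):
        for p5 in range(6):
            pr = b5c[c5] * b5p[p5]
            if c5 >= 2 or p5 >= 4:
                p_infeasible_5 += pr
            elif c5 == 0 and p5 <= 2:
                p_cohort2_n12 += pr
            else:  # expand to seven
                for c2 in range(3):
                    for p2 in range(3):
                        pr2 = pr * b2c[c2] * b2p[p2]
                        if c5 + c2 <= 1 and p5 + p2 <= 3:
                            p_cohort2_n14 += pr2
                        else:
                            p_infeasible_7 += pr2
    # cohort 2 at the higher dose: fail -> level 1 is MTD
    p_fail2 = 1.0 - sum(
        stats.binom.pmf(c, 7, pc2) * stats.binom.pmf(p, 7, pp2)
        for c in range(2)
        for p in range(4)
    )
    p_reach = p_cohort2_n12 + p_cohort2_n14
    return {
        "infeasible": p_infeasible_5 + p_infeasible_7,
        "mtd1": p_reach * p_fail2,
        "mtd2": p_reach * (1.0 - p_fail2),
        "mean_n": (
            5 * p_infeasible_5
            + 7 * p_infeasible_7
            + 12 * p_cohort2_n12
            + 14 * p_cohort2_n14
        ),
    }
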