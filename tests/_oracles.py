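"""Independent brute-force oracles used only by the test suite.

These are deliberately written as plain-Python literal translations of the
definitions (loops, sorted(), explicit counting) so they share no code
path with the vectorized implementations they check.
"""

import math


def qini_brute_force(phi, scores, treated, survived, ids):
    """Adjusted qini index at phi by explicit enumeration."""
    records = list(zip(scores, treated, survived, ids))
    t_arm = sorted((r for r in records if r[1] == 1), key=lambda r: (-r[0], r[3]))
    c_arm = sorted((r for r in records if r[1] == 0), key=lambda r: (-r[0], r[3]))
    N_t, N_c = len(t_arm), len(c_arm)
    n_t = math.ceil(phi * N_t)
    n_c = math.ceil(phi * N_c)
    n_t1 = sum(r[2] for r in t_arm[:n_t])
    n_c1 = sum(r[2] for r in c_arm[:n_c])
    return n_t1 / N_t - (n_c1 * n_t) / (N_t * n_c)


def kdigo_rule_table(scr_ratio, scr_increase_48h, scr_absolute,
                     uo_6h, uo_12h, uo_24h, anuria_12h, on_rrt):
    """KDIGO stage by checking every rule independently and taking the max."""
    candidates = [0]
    if on_rrt:
        candidates.append(3)
    if scr_ratio >= 3.0:
        candidates.append(3)
    if scr_absolute >= 4.0:
        candidates.append(3)
    if 2.0 <= scr_ratio < 3.0:
        candidates.append(2)
    if 1.5 <= scr_ratio < 2.0:
        candidates.append(1)
    if scr_increase_48h >= 0.3:
        candidates.append(1)
    if anuria_12h:
        candidates.append(3)
    if uo_24h < 0.3:
        candidates.append(3)
    if uo_12h < 0.5:
        candidates.append(2)
    if uo_6h < 0.5:
        candidates.append(1)
    return max(candidates)


def greedy_match_reference(propensity, treated_ids, control_ids, caliper=None):
    """Greedy 1:1 matching by the literal protocol definition: treated in
    descending propensity (ties: lowest id), nearest remaining control by
    absolute logit difference (ties: lowest id), without replacement."""

    def logit(p):
        return math.log(p / (1 - p))

    remaining = set(control_ids)
    pairs = []
    for t in sorted(treated_ids, key=lambda i: (-propensity[i], i)):
        if not remaining:
            break
        best = min(remaining, key=lambda c: (abs(logit(propensity[c]) - logit(propensity[t])), c))
        dist = abs(logit(propensity[best]) - logit(propensity[t]))
        if caliper is None or dist <= caliper:
            remaining.discard(best)
            pairs.append((t, best))
    return pairs
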