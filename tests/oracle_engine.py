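"""Independent straight-line re-implementation of the shift fill rules.

Used as the oracle against which the production shift engine is checked on
small randomized instances.  Written deliberately in plain scalar Python,
following the documented rules step by step:

1. A unit-role is triggered iff required > 0 and
   (required - available)/required > tolerance.
2. Triggered units are filled back up to the tolerance boundary
   (1 - tolerance) x required, in whole blocks.
3. Floating (if allowed, within a specialty group): recipients in
   descending shortfall order (ties by index); each recipient repeatedly
   takes as many blocks as it needs (or the donor can spare) from the donor
   with the largest current whole-block surplus (ties by index); donors
   never drop below their own requirement.
4. Remaining triggered units request ceil(gap/block) blocks; each block is
   filled by the bank with probability p_bank, declined blocks go once to
   the agency with probability p_agency.
"""

from __future__ import annotations

import math

EPS = 1e-9


def oracle_resolve(
    required,  # list of [rn, na] hours per unit
    available,  # list of [rn, na] hours per unit
    groups,  # list of group labels per unit
    tolerance: float,
    block: float,
    p_bank,  # [rn, na]
    p_agency,  # [rn, na]
    u_bank,  # dict (unit, role) -> list of uniforms
    u_agency,
    allow_floating: bool,
):
    n = len(required)
    avail = [[available[i][r] for r in range(2)] for i in range(n)]
    floated_in = [[0.0, 0.0] for _ in range(n)]
    floated_out = [[0.0, 0.0] for _ in range(n)]
    bank = [[0.0, 0.0] for _ in range(n)]
    agency = [[0.0, 0.0] for _ in range(n)]

    def is_triggered(i, r):
        req = required[i][r]
        return req > 0 and (req - avail[i][r]) / req > tolerance + EPS

    for r in range(2):
        triggered = [i for i in range(n) if is_triggered(i, r)]

        if allow_floating:
            for g in sorted(set(groups)):
                members = [i for i in range(n) if groups[i] == g]
                if len(members) < 2:
                    continue
                recs = [i for i in members if i in triggered]
                recs.sort(key=lambda i: (-(required[i][r] - avail[i][r]), i))
                for rec in recs:
                    target = (1.0 - tolerance) * required[rec][r]
                    while avail[rec][r] < target - EPS:
                        best, best_blocks = None, 0
                        for d in members:
                            if d == rec:
                                continue
                            surplus_blocks = math.floor(
                                (avail[d][r] - required[d][r]) / block + EPS
                            )
                            if surplus_blocks > best_blocks:
                                best, best_blocks = d, surplus_blocks
                        if best is None:
                            break
                        need = math.ceil((target - avail[rec][r]) / block - EPS)
                        give = min(need, best_blocks)
                        hours = give * block
                        avail[best][r] -= hours
                        avail[rec][r] += hours
                        floated_out[best][r] += hours
                        floated_in[rec][r] += hours

        for i in triggered:
            gap = (1.0 - tolerance) * required[i][r] - avail[i][r]
            if gap <= EPS:
                continue
            k = math.ceil(gap / block - EPS)
            ub, ua = u_bank[(i, r)], u_agency[(i, r)]
            for j in range(k):
                if ub[j] < p_bank[r]:
                    bank[i][r] += block
                    avail[i][r] += block
                elif ua[j] < p_agency[r]:
                    agency[i][r] += block
                    avail[i][r] += block

    return {
        "achieved": avail,
        "floated_in": floated_in,
        "floated_out": floated_out,
        "bank": bank,
        "agency": agency,
    }
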