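"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or closed
forms, sharing no code with the implementation paths they check.
"""

from itertools import product

from ovatriage.accuracy import TestId
from ovatriage.decision_tree import PathwayDefinition, PathwayMode


def enumerate_pathway(pathway: PathwayDefinition, accuracy, age_group, prevalence):
    """Four-class probabilities by enumerating every joint atom.

    Atoms: disease status x blood-test band x ultrasound result (at most 12).
    The triage rule is re-stated literally per atom.
    """
    sens_u, spec_u = accuracy.lookup(TestId.USS, age_group, "abnormal")
    banded = pathway.mode is PathwayMode.SEQUENTIAL and pathway.moderate_label is not None
    if banded:
        sens_m, spec_m = accuracy.lookup(pathway.first_test, age_group, pathway.moderate_label)
        sens_h, spec_h = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        bands_oc = {"low": 1 - sens_m, "mod": sens_m - sens_h, "high": sens_h}
        bands_no = {"low": spec_m, "mod": spec_h - spec_m, "high": 1 - spec_h}
    else:
        sens_b, spec_b = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        bands_oc = {"low": 1 - sens_b, "high": sens_b}
        bands_no = {"low": spec_b, "high": 1 - spec_b}

    p = {"tp": 0.0, "fn": 0.0, "tn": 0.0, "fp": 0.0}
    for disease, band, uss_pos in product((True, False), bands_oc, (True, False)):
        p_dis = prevalence if disease else 1 - prevalence
        p_band = (bands_oc if disease else bands_no)[band]
        p_uss = (sens_u if disease else 1 - spec_u) if uss_pos else (
            1 - sens_u if disease else spec_u
        )
        mass = p_dis * p_band * p_uss
        if pathway.mode is PathwayMode.CONCURRENT:
            referred = band == "high" or uss_pos
        elif banded:
            referred = band == "high" or (band == "mod" and uss_pos)
        else:
            referred = band == "high" and uss_pos
        if disease:
            p["tp" if referred else "fn"] += mass
        else:
            p["fp" if referred else "tn"] += mass
    return p


def exhaustive_frontier(points):
    """(dominated, extendedly dominated) id sets by direct definition.

    An option is dominated if some other option has at least its QALYs at no
    more cost (one strictly better; exact ties defer to the lower id).  A
    non-dominated option is extendedly dominated if a convex combination of
    two other non-dominated options delivers at least its QALYs at no more
    cost, strictly better in one.
    """
    dominated = set()
    for pid, q, c in points:
        for pjd, qj, cj in points:
            if pjd == pid:
                continue
            if qj == q and cj == c:
                if pjd < pid:
                    dominated.add(pid)
            elif qj >= q and cj <= c:
                dominated.add(pid)
    survivors = [p for p in points if p[0] not in dominated]
    ext = set()
    for pid, q, c in survivors:
        for (ia, qa, ca) in survivors:
            for (ib, qb, cb) in survivors:
                if pid in (ia, ib) or ia == ib:
                    continue
                denom = qb - qa
                if denom == 0:
                    continue
                lam = (q - qa) / denom
                if not 0.0 <= lam <= 1.0:
                    continue
                blend_cost = ca + lam * (cb - ca)
                if blend_cost < c - 1e-9:
                    ext.add(pid)
    return dominated, ext
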