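"""Event loop for GARD population dynamics.

Written in a numba-compilable subset of numpy; compiled with ``numba.njit``
when numba imports, otherwise run as plain Python (identical semantics,
adequate for the small problem sizes the tests use).

State per vesicle: integer lipid counts n, size, the catalysis vector
c = beta @ n and its sum.  A growth event adds one lipid of type t with
probability proportional to w_t = 1 + c_t / size, chosen on the vesicle with
the largest share of the total propensity (Gillespie-style selection across
the population).  A vesicle reaching n_max splits into two exact halves by
an urn draw (multivariate hypergeometric); both children enter and one
uniformly random member of the enlarged population is culled.
"""

import numpy as np


def _simulate_core_impl(beta, n_max, population, n_divisions, seed, record, record_interval):
    np.random.seed(seed)
    ng = beta.shape[0]
    half = n_max // 2
    colsum = np.zeros(ng)
    for t in range(ng):
        s = 0.0
        for i in range(ng):
            s += beta[i, t]
        colsum[t] = s

    counts = np.zeros((population, ng), dtype=np.int64)
    sizes = np.zeros(population, dtype=np.int64)
    cat = np.zeros((population, ng))
    catsum = np.zeros(population)

    # initial vesicles: half-size, uniformly random lipid types
    for v in range(population):
        for _ in range(half):
            t = int(np.random.random() * ng)
            if t >= ng:
                t = ng - 1
            counts[v, t] += 1
        sizes[v] = half
        for i in range(ng):
            s = 0.0
            for k in range(ng):
                s += beta[i, k] * counts[v, k]
            cat[v, i] = s
        catsum[v] = cat[v].sum()

    child = np.zeros(ng, dtype=np.int64)
    remaining = np.zeros(ng, dtype=np.int64)
    divisions = 0
    records_written = 0
    while divisions < n_divisions:
        # total addition propensity per vesicle: ng + catsum/size
        wtot_all = 0.0
        for v in range(population):
            wtot_all += ng + catsum[v] / sizes[v]
        r = np.random.random() * wtot_all
        v = population - 1
        acc = 0.0
        for u in range(population):
            acc += ng + catsum[u] / sizes[u]
            if r < acc:
                v = u
                break
        # lipid type within vesicle v: w_t = 1 + cat[v, t]/size
        wv = ng + catsum[v] / sizes[v]
        r2 = np.random.random() * wv
        t = ng - 1
        acc = 0.0
        for u in range(ng):
            acc += 1.0 + cat[v, u] / sizes[v]
            if r2 < acc:
                t = u
                break
        counts[v, t] += 1
        sizes[v] += 1
        for i in range(ng):
            cat[v, i] += beta[i, t]
        catsum[v] += colsum[t]

        if sizes[v] == n_max:
            # split: draw half lipids without replacement (urn)
            for i in range(ng):
                child[i] = 0
                remaining[i] = counts[v, i]
            rem_total = n_max
            for _ in range(half):
                r3 = np.random.random() * rem_total
                pick = ng - 1
                acc2 = 0.0
                for u in range(ng):
                    acc2 += remaining[u]
                    if r3 < acc2:
                        pick = u
                        break
                child[pick] += 1
                remaining[pick] -= 1
                rem_total -= 1
            # slot v takes child 1; the second child and all current slots
            # compete for survival: cull one of population+1 entities
            cull = int(np.random.random() * (population + 1))
            if cull > population:
                cull = population
            for i in range(ng):
                counts[v, i] = child[i]
            sizes[v] = half
            if cull != population:
                # second child replaces the culled slot (possibly v itself)
                for i in range(ng):
                    counts[cull, i] = remaining[i]
                sizes[cull] = half
            # refresh cached catalysis for the touched slots
            for slot in (v, cull if cull != population else v):
                for i in range(ng):
                    s = 0.0
                    for k in range(ng):
                        s += beta[i, k] * counts[slot, k]
                    cat[slot, i] = s
                catsum[slot] = cat[slot].sum()
            divisions += 1
            if record_interval > 0 and divisions % record_interval == 0:
                if records_written < record.shape[0]:
                    for i in range(ng):
                        s = 0.0
                        for u in range(population):
                            s += counts[u, i] / sizes[u]
                        record[records_written, i] = s / population
                    records_written += 1

    out = np.zeros(ng)
    for v in range(population):
        for i in range(ng):
            out[i] += counts[v, i] / sizes[v]
    out /= population
    return out


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    simulate_core = njit(cache=False)(_simulate_core_impl)
except ImportError:  # pragma: no cover
    simulate_core = _simulate_core_impl
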