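"""Independent literal reference for DMR region calling on small grids.

Re-evaluates the region rules naively, site by site, with no shared code or
vectorization: significant same-sign sites (anchors) chain while no
opposite-sign-diff site lies between consecutive anchors, their separation is
<= dis_merge_bp, and the running significant fraction over all spanned grid
sites stays >= pct_sig (ties extend); each resulting run must then pass the
minlen / minCG / pct.sig / delta filters. This defines the reference
behavior the production caller must reproduce.
"""
from __future__ import annotations

import numpy as np


def brute_force_dmrs(pos, diff, p, params):
    """Return sorted tuples (chrom, start, end, direction, n_cpg, mean_diff, n_sig)."""
    pos = [int(x) for x in pos]
    diff = [float(x) for x in diff]
    p = [float(x) for x in p]
    n = len(pos)
    out = []
    for d, name in ((1.0, "hyper"), (-1.0, "hypo")):
        def is_anchor(i):
            return (
                p[i] <= params.p_threshold
                and abs(diff[i]) >= params.delta
                and diff[i] != 0
                and np.sign(diff[i]) == d
            )

        def is_barrier(i):
            return diff[i] != 0 and np.sign(diff[i]) == -d

        anchors = [i for i in range(n) if is_anchor(i)]
        runs = []
        run: list[int] = []
        for a in anchors:
            if run:
                prev = run[-1]
                blocked = any(is_barrier(k) for k in range(prev + 1, a))
                too_far = pos[a] - (pos[prev] + 1) > params.dis_merge_bp
                n_sig_if = sum(1 for k in range(run[0], a + 1) if is_anchor(k))
                n_all_if = a - run[0] + 1
                diluted = n_sig_if < params.pct_sig * n_all_if
                if blocked or too_far or diluted:
                    runs.append(run)
                    run = []
            run.append(a)
        if run:
            runs.append(run)
        for r in runs:
            lo, hi = r[0], r[-1]
            n_cpg = hi - lo + 1
            n_sig = sum(1 for k in range(lo, hi + 1) if is_anchor(k))
            length = pos[hi] + 1 - pos[lo]
            md = float(np.mean(diff[lo : hi + 1]))
            if (
                length >= params.minlen_bp
                and n_cpg >= params.min_cg
                and n_sig >= params.pct_sig * n_cpg
                and abs(md) >= params.delta
                and np.sign(md) == d
            ):
                out.append(("chrT", pos[lo], pos[hi] + 1, name, n_cpg, round(md, 9), n_sig))
    return sorted(out)


def random_site_grid(seed: int, max_sites: int = 50):
    """A random small per-site test table exercising the region rules."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_sites + 1))
    # clustered positions so that runs, gaps just around dis_merge, and long
    # voids all occur
    gaps = rng.choice([5, 20, 45, 50, 51, 60, 200], size=n, p=[0.25, 0.2, 0.15, 0.1, 0.1, 0.1, 0.1])
    pos = np.cumsum(gaps) + rng.integers(0, 50)
    diff = rng.uniform(-0.5, 0.5, n)
    p = np.where(
        rng.random(n) < 0.5,
        10.0 ** rng.uniform(-30, -16, n),
        10.0 ** rng.uniform(-15, 0, n),
    )
    return pos, diff, p


def called_tuples(dmrs):
    return sorted(
        (
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.direction,
            r.n_cpg,
            round(r.mean_diff, 9),
            r.n_sig,
        )
        for r in dmrs
    )
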