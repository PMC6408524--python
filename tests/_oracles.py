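"""Independent brute-force oracles used to check the package.

These are deliberately written from the conventions alone (string-level
pattern construction, exhaustive enumeration, exact integer arithmetic)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import product
from math import comb

from zfndesign._iupac import IUPAC_SETS, revcomp

# site order is the reverse of protein (amino->carboxy) module order
_COMPOSITIONS = {6: (2, 2, 2), 5: (2, 2, 1)}


def _site_pattern(modules, plan, finger_count):
    """Full site pattern (or None if the plan is infeasible for these
    modules): module triplets concatenated 5'->3' with an 'N' inserted
    at each skipped junction; a skip landing inside a two-finger module
    requires that module to be skip-capable."""
    triplets = []
    owner = []  # module index owning each triplet boundary's 5' side
    for mi, m in enumerate(modules):
        for t in m.triplets:
            triplets.append(t)
            owner.append(mi)
    boundaries = sorted(
        finger_count - int(lbl.split("-")[0][1:]) for lbl in plan.skipped_junctions
    )
    for b in boundaries:
        if owner[b - 1] == owner[b] and not modules[owner[b]].skip_capable_internal:
            return None
    out = []
    for i, t in enumerate(triplets):
        if i in boundaries:
            out.append("N")
        out.append(t)
    return "".join(out)


def _matches(pattern: str, window: str) -> bool:
    if len(pattern) != len(window):
        return False
    if set(pattern) <= set("ACGT"):
        return pattern == window
    return all(IUPAC_SETS[s] <= IUPAC_SETS[p] for p, s in zip(pattern, window))


def brute_force_sites(seq, archive, finger_count, plans, composition=None):
    """Every (start, end, strand, plan, module ids) matching the
    sequence, by exhaustive enumeration of offsets x strands x plans x
    ordered module triples."""
    seq = seq.upper()
    comp = tuple(composition or _COMPOSITIONS[finger_count])
    site_comp = tuple(reversed(comp))
    pools = [[m for m in archive.modules if m.n_fingers == nf] for nf in site_comp]
    found = set()
    n = len(seq)
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        for plan in plans:
            span = 3 * finger_count + len(plan.skipped_junctions)
            for modules in product(*pools):
                pattern = _site_pattern(modules, plan, finger_count)
                if pattern is None:
                    continue
                for o in range(n - span + 1):
                    if _matches(pattern, oriented[o : o + span]):
                        start = o if strand == "+" else n - (o + span)
                        found.add(
                            (start, start + span, strand, plan, tuple(m.id for m in modules))
                        )
    return found


_ARCH_STRANDS = {"CC": ("-", "+"), "NC": ("+", "+"), "CN": ("-", "-"), "NN": ("+", "-")}


def brute_force_pairs(site_tuples, configs):
    """All (left site, right site, config label) design keys by trying
    every ordered pair of sites against every configuration."""
    designs = set()
    for a, b in product(site_tuples, repeat=2):
        for cfg in configs:
            ls, rs = _ARCH_STRANDS[cfg.arch.value]
            if a[2] != ls or b[2] != rs:
                continue
            if a[3] != cfg.left_skip or b[3] != cfg.right_skip:
                continue
            if b[0] - a[1] != cfg.gap_bp:
                continue
            designs.add((a[:2] + (a[2], a[4]), b[:2] + (b[2], b[4]), cfg.label()))
    return designs


def fisher_two_sided(t_ind, t_non, c_ind, c_non):
    """Two-sided Fisher exact p by direct hypergeometric enumeration.

    All table weights C(r, a) * C(N - r, c - a) for totals <= ~10^3 are
    below 2^53, so float arithmetic on them is exact.  Tables whose
    probability is at most (1 + 1e-7) times the observed table's are
    summed, matching the conventional two-sided definition.
    """
    r = t_ind + t_non
    N = r + c_ind + c_non
    c = t_ind + c_ind
    lo, hi = max(0, r + c - N), min(r, c)
    weights = [comb(r, a) * comb(N - r, c - a) for a in range(lo, hi + 1)]
    w_obs = weights[t_ind - lo]
    total = comb(N, c)
    return sum(w for w in weights if w <= w_obs * (1 + 1e-7)) / total


def brute_force_clusters(events, window_bp):
    """Cluster membership by connected components of the 'within
    window_bp on the same chromosome' graph."""
    evs = list(events)
    n = len(evs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            if evs[i].chrom == evs[j].chrom and abs(evs[i].pos - evs[j].pos) <= window_bp:
                union(i, j)
    groups = {}
    for i, e in enumerate(evs):
        groups.setdefault(find(i), []).append(e)
    return {
        frozenset((e.chrom, e.pos, e.strand, e.replicate, e.arm) for e in g)
        for g in groups.values()
    }
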