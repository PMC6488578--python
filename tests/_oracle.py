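"""Independent brute-force oracles used by the test suite.

The scanner oracle enumerates every anchored Φ1..Φ4 placement of every
class and checks the slot constraints directly, with its own hardcoded
class tables — it shares no code with the production scanner.
"""

from __future__ import annotations

PHI = set("LIVMF")
TA = set("TA")
NOPW_BAD = set("PWX")  # unknown residues never satisfy a [^PW] slot
BULKY = set("LFM")

#: class -> inter-Φ distances (Φ1→Φ2, Φ2→Φ3, Φ3→Φ4)
GAPS = {
    "1a": (4, 3, 2), "1b": (3, 3, 2), "2": (2, 3, 2),
    "1c": (4, 4, 2), "1d": (3, 4, 2), "3": (3, 4, 3), "4": (4, 3, 4),
}
#: class -> ([^PW]-restricted spacer indices within gap 2, within gap 3)
NOPW = {
    "1a": ((0, 1), (0,)), "1b": ((0, 1), (0,)), "2": ((0, 1), (0,)),
    "1c": ((0, 1, 2), (0,)), "1d": ((0, 1, 2), (0,)),
    "3": ((1, 2), (0, 1)), "4": ((0, 1), ()),
}
TA_CLASSES = {"1a", "1b", "1c", "1d", "2", "3"}


def _forward_hits(s: str):
    hits = set()
    L = len(s)
    for cid, (g1, g2, g3) in GAPS.items():
        for p1 in range(1, L + 1):
            p2, p3, p4 = p1 + g1, p1 + g1 + g2, p1 + g1 + g2 + g3
            if p4 > L:
                continue
            ta = 0
            ok = True
            for k, p in enumerate((p1, p2, p3, p4)):
                aa = s[p - 1]
                if aa in PHI:
                    continue
                if cid in TA_CLASSES and k < 2 and aa in TA and ta == 0:
                    ta = 1
                    continue
                ok = False
                break
            if not ok:
                continue
            gap2 = [s[p - 1] for p in range(p2 + 1, p3)]
            gap3 = [s[p - 1] for p in range(p3 + 1, p4)]
            if any(gap2[i] in NOPW_BAD for i in NOPW[cid][0]):
                continue
            if any(gap3[i] in NOPW_BAD for i in NOPW[cid][1]):
                continue
            if cid == "4" and "P" not in gap3:
                continue
            hits.add((cid, p1, p2, p3, p4, bool(ta)))
    return hits


def oracle_scan(seq: str) -> set:
    """All (class_id, direction, phi_positions, ta_used) placements."""
    out = set()
    L = len(seq)
    for cid, p1, p2, p3, p4, ta in _forward_hits(seq):
        out.add((cid, "forward", (p1, p2, p3, p4), ta))
    rev = seq[::-1]
    for cid, p1, p2, p3, p4, ta in _forward_hits(rev):
        if cid not in ("1a", "1c") or ta:
            continue
        if not ({rev[p3 - 1], rev[p4 - 1]} & BULKY):
            continue
        flip = lambda p: L - p + 1
        out.add((cid + "-R", "reverse",
                 (flip(p1), flip(p2), flip(p3), flip(p4)), False))
    return out


def oracle_groups(starts: list[int], delta: int) -> list[list[int]]:
    """Connected components of the |start_i − start_j| < delta graph."""
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) < delta:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(starts[i])
    return sorted((sorted(v) for v in comps.values()), key=lambda g: g[0])
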