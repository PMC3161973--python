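"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way and shares
no code with the package: exact integer arithmetic for the tag-count
statistic, naive string scans for tag extraction, exhaustive Hamming
scans for mapping, and a literal restatement of the QC rules.
"""

from __future__ import annotations

import math
from fractions import Fraction

_LOG2 = math.log(2.0)


def int_log(n: int) -> float:
    """Natural log of a positive (possibly huge) integer."""
    if n <= 0:
        raise ValueError("int_log needs a positive integer")
    bits = n.bit_length()
    if bits <= 900:
        return math.log(n)
    shift = bits - 900
    return math.log(n >> shift) + shift * _LOG2


def ac_point_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """Exact p(y|x) = C(x+y, y) N2^y N1^(x+1) / (N1+N2)^(x+y+1)."""
    num = math.comb(x + y, y) * (N2**y) * (N1 ** (x + 1))
    return Fraction(num, (N1 + N2) ** (x + y + 1))


def ac_two_sided_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """Exact two-sided p-value by direct rational summation."""
    lower = sum(ac_point_exact(x, k, N1, N2) for k in range(y + 1))
    upper = 1 - sum(ac_point_exact(x, k, N1, N2) for k in range(y))
    return min(Fraction(1), 2 * min(lower, upper))


def ac_log_two_sided_grid(x: int, y_max: int, N1: int, N2: int) -> list[float]:
    """log of the exact two-sided p-value for all y in 0..y_max at fixed x.

    Uses integer numerators over the common denominator
    D = (N1+N2)^(x+y_max+1), so every tail sum is exact; returns natural
    logs (full precision even where the p-value underflows a double).
    """
    s = N1 + N2
    denom = s ** (x + y_max + 1)
    pow2 = [N2**k for k in range(y_max + 1)]
    pow12 = [s**k for k in range(y_max + 1)]
    n1x = N1 ** (x + 1)
    combs = [1]
    for k in range(y_max):
        combs.append(combs[-1] * (x + k + 1) // (k + 1))
    nums = [combs[k] * pow2[k] * n1x * pow12[y_max - k] for k in range(y_max + 1)]
    cum = []
    acc = 0
    for v in nums:
        acc += v
        cum.append(acc)
    log_denom = int_log(denom)
    out = []
    for y in range(y_max + 1):
        lower = cum[y]
        upper = denom - (cum[y - 1] if y > 0 else 0)
        p_num = min(denom, 2 * min(lower, upper))
        out.append(int_log(p_num) - log_denom)
    return out


def scan_tags(sequence: str, anchor: str = "CATG", downstream: int = 17) -> list[tuple[int, str]]:
    """Naive brute-force scan for anchor+downstream tags (N-free)."""
    tag_len = len(anchor) + downstream
    out = []
    for i in range(len(sequence) - tag_len + 1):
        if sequence[i : i + len(anchor)] == anchor:
            tag = sequence[i : i + tag_len]
            if "N" not in tag:
                out.append((i, tag))
    return out


def build_index_bruteforce(records: list[tuple[str, str]]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gene_id, seq in records:
        for _, tag in scan_tags(seq):
            index.setdefault(tag, set()).add(gene_id)
    return index


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def map_tag_bruteforce(tag: str, index: dict[str, set[str]]) -> tuple[set[str], int | None]:
    """Exhaustive Hamming scan: (gene set, mismatch tier) or (empty, None)."""
    exact: set[str] = set()
    mm1: set[str] = set()
    for ref_tag, genes in index.items():
        d = hamming(tag, ref_tag)
        if d == 0:
            exact |= genes
        elif d == 1:
            mm1 |= genes
    if exact:
        return exact, 0
    if mm1:
        return mm1, 1
    return set(), None


def map_library_bruteforce(
    tags: list[str], index: dict[str, set[str]]
) -> dict[str, tuple[set[str], int | None]]:
    """Exhaustive Hamming scan of every query against every reference tag,
    vectorized over byte arrays (independent of the package's
    neighborhood-enumeration mapper)."""
    import numpy as np

    ref_tags = list(index)
    ref = np.frombuffer("".join(ref_tags).encode(), dtype=np.uint8).reshape(len(ref_tags), -1)
    out = {}
    for tag in tags:
        q = np.frombuffer(tag.encode(), dtype=np.uint8)
        d = (ref != q).sum(axis=1)
        exact = np.flatnonzero(d == 0)
        mm1 = np.flatnonzero(d == 1)
        if exact.size:
            genes = set().union(*(index[ref_tags[i]] for i in exact))
            out[tag] = (genes, 0)
        elif mm1.size:
            genes = set().union(*(index[ref_tags[i]] for i in mm1))
            out[tag] = (genes, 1)
        else:
            out[tag] = (set(), None)
    return out


def clean_tag_bruteforce(tag: str, count: int, adapters: list[str]) -> str | None:
    """Literal restatement of the QC rules; returns removal reason or None."""
    if len(tag) != 21 or not tag.startswith("CATG"):
        return "empty"
    if any(a in tag for a in adapters):
        return "adapter"
    if "N" in tag:
        return "contains_n"
    var = tag[4:]
    longest = max(
        (len(run) for run in _runs(var)),
        default=0,
    )
    if len(set(var)) <= 2 or longest >= 15:
        return "low_complexity"
    if count == 1:
        return "singleton"
    return None


def _runs(s: str) -> list[str]:
    out = []
    cur = s[0]
    for ch in s[1:]:
        if ch == cur[-1]:
            cur += ch
        else:
            out.append(cur)
            cur = ch
    out.append(cur)
    return out


def pearson_textbook(a: list[float], b: list[float]) -> float:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def bh_stepup(ps: list[float]) -> list[float]:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, ps[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj
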