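"""Nested secondary-structure folding by base-pair maximization.

Novel-miRNA hairpin calls need only the pairing topology of the candidate
window (which arm holds the mature, how many of its bases pair with the star
region, loop size), so the folding engine is a Nussinov-style dynamic program
maximizing Watson-Crick plus G:U wobble pairs under a minimum-loop constraint.
Pseudoknots are excluded by construction.  A thermodynamic engine can be
swapped in through the ``fold_fn`` plug-in point of the discovery step.
"""

from __future__ import annotations

from dataclasses import dataclass

_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
    ("G", "U"), ("U", "G"),
}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble (T treated as U)."""
    return (a, b) in _PAIRS


def max_pairing(seq: str, min_loop: int = 3) -> tuple[int, list[tuple[int, int]]]:
    """Maximum number of nested base pairs and one attaining structure.

    Returns (pair count, pairs) with 0-based (i, j) index pairs, i < j and
    j - i > min_loop.  Bottom-up DP over subsequence length with traceback.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        return 0, []
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if can_pair(seq[k], seq[j]):
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + 1 + dp[k + 1][j - 1]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if can_pair(seq[k], seq[j]):
                left = dp[i][k - 1] if k > i else 0
                if left + 1 + dp[k + 1][j - 1] == dp[i][j]:
                    pairs.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return dp[0][n - 1], sorted(pairs)


@dataclass
class HairpinCandidate:
    """Evidence for a candidate miRNA precursor hairpin.

    ``arm`` is '5p' when the mature sits upstream of its star partner region.
    ``mature_star_pairs`` counts mature bases paired into the star region.
    """

    window: str
    pairs: list[tuple[int, int]]
    mature_start: int  # 0-based within window
    mature_end: int    # exclusive
    arm: str
    star_start: int
    star_end: int
    mature_star_pairs: int
    max_consecutive_unpaired: int
    loop_length: int
    accepted: bool
    reason: str


def evaluate_hairpin(
    window: str,
    mature_start: int,
    mature_end: int,
    min_loop: int = 3,
    min_paired: int = 16,
    max_unpaired_run: int = 4,
    fold_fn=max_pairing,
) -> HairpinCandidate:
    """Fold a window and decide whether the placed mature read looks miRNA-like.

    Acceptance rules: the mature must lie entirely on one arm (all of its
    pairing partners on the same side, none internal), pair >= ``min_paired``
    bases with the star region, contain no run of unpaired bases longer than
    ``max_unpaired_run``, and close a terminal loop of >= ``min_loop`` nt.
    """

    def reject(reason: str, **kw) -> HairpinCandidate:
        return HairpinCandidate(
            window=window, pairs=kw.get("pairs", []), mature_start=mature_start,
            mature_end=mature_end, arm=kw.get("arm", ""), star_start=kw.get("star_start", -1),
            star_end=kw.get("star_end", -1), mature_star_pairs=kw.get("msp", 0),
            max_consecutive_unpaired=kw.get("mcu", mature_end - mature_start),
            loop_length=kw.get("loop", -1), accepted=False, reason=reason,
        )

    _, pairs = fold_fn(window, min_loop)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    mature_idx = range(mature_start, mature_end)
    partners = [partner[i] for i in mature_idx if i in partner]
    internal = [p for p in partners if mature_start <= p < mature_end]
    if internal:
        return reject("mature pairs with itself", pairs=pairs)
    if not partners:
        return reject("mature entirely unpaired", pairs=pairs)
    up = [p for p in partners if p < mature_start]
    down = [p for p in partners if p >= mature_end]
    if up and down:
        return reject("mature pairs into both arms", pairs=pairs)
    arm = "5p" if down else "3p"
    star_positions = down or up
    star_start, star_end = min(star_positions), max(star_positions) + 1
    msp = len(partners)

    # longest run of unpaired mature bases
    run = mcu = 0
    for i in mature_idx:
        if i in partner:
            run = 0
        else:
            run += 1
            mcu = max(mcu, run)

    # terminal loop closed by the innermost mature<->star pair
    inner = min(
        ((i, partner[i]) for i in mature_idx if i in partner),
        key=lambda ij: abs(ij[1] - ij[0]),
    )
    loop = abs(inner[1] - inner[0]) - 1

    ok = msp >= min_paired and mcu <= max_unpaired_run and loop >= min_loop
    reason = "accepted" if ok else (
        f"pairs={msp}<{min_paired}" if msp < min_paired
        else (f"unpaired run {mcu}>{max_unpaired_run}" if mcu > max_unpaired_run
              else f"loop {loop}<{min_loop}")
    )
    return HairpinCandidate(
        window=window, pairs=pairs, mature_start=mature_start, mature_end=mature_end,
        arm=arm, star_start=star_start, star_end=star_end, mature_star_pairs=msp,
        max_consecutive_unpaired=mcu, loop_length=loop, accepted=ok, reason=reason,
    )
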