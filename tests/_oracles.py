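"""Independent reference implementations used only to check the aligner.

``affine_local_score`` is a memoized-recursion formulation of optimal
local alignment under affine gap costs (gap of length k costs
open + k*extend), written independently of the production kernel.
``biopython_local_score`` wraps Bio.Align.PairwiseAligner as a second,
fully external cross-check.
"""

from functools import lru_cache

from Bio import Align

MATCH_STATE, GAP_Q, GAP_T = 0, 1, 2


def affine_local_score(query: str, target: str, match: int = 1,
                       mismatch: int = 3, gap_open: int = 5,
                       gap_extend: int = 2) -> int:
    """Best local alignment score by recursion over alignment suffixes."""
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def ending_at(i: int, j: int, state: int) -> float:
        # best score of an alignment path ending at (i, j) in `state`;
        # may start anywhere (local): the diagonal move may begin a path
        if state == MATCH_STATE:
            if i == 0 or j == 0:
                return float("-inf")
            sub = match if query[i - 1] == target[j - 1] else -mismatch
            prev = max(
                0,
                ending_at(i - 1, j - 1, MATCH_STATE),
                ending_at(i - 1, j - 1, GAP_Q),
                ending_at(i - 1, j - 1, GAP_T),
            )
            return prev + sub
        if state == GAP_Q:  # gap in query: consumes target
            if j == 0:
                return float("-inf")
            return max(
                ending_at(i, j - 1, MATCH_STATE) - first,
                ending_at(i, j - 1, GAP_Q) - gap_extend,
            )
        if i == 0:  # GAP_T: gap in target, consumes query
            return float("-inf")
        return max(
            ending_at(i - 1, j, MATCH_STATE) - first,
            ending_at(i - 1, j, GAP_T) - gap_extend,
        )

    best = 0.0
    for i in range(len(query) + 1):
        for j in range(len(target) + 1):
            for state in (MATCH_STATE, GAP_Q, GAP_T):
                best = max(best, ending_at(i, j, state))
    ending_at.cache_clear()
    return int(best)


def biopython_local_score(query: str, target: str, match: int = 1,
                          mismatch: int = 3, gap_open: int = 5,
                          gap_extend: int = 2) -> int:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = -mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    try:
        return int(aligner.score(query, target))
    except ValueError:
        return 0
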