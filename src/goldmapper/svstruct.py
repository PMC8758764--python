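"""Insertion discovery from haplotype pairs and inverted-repeat analysis.

Two related sequence problems solved at desk scale:

1. *Insertion discovery* — given the reference (d) and alternate (G)
   haplotype sequences of a locus, find the inserted segment.  K-mers
   unique in both sequences serve as anchors (MUM-like); a collinear
   chain is selected by longest-increasing-subsequence over anchor
   positions, and any gap present in the alternate but absent from the
   reference between chained anchors is reported as an insertion.  The
   breakpoint is left-aligned: the reference base immediately left of
   the gap.  Unique-anchor chaining is exact when the insertion flanks
   are unique, which is the regime the method assumes.

2. *Inverted-repeat characterization* — given an inserted sequence,
   find two arms in head-to-head orientation (the stem of a potential
   DNA cruciform) and the loop between them.  Word matches between the
   sequence and its reverse complement are merged into near-diagonal
   runs, chained across small diagonal shifts (single-base indels), and
   the boundaries polished by complement-aware extension.  The two arms
   are then compared by global alignment of arm1 against the reverse
   complement of arm2 (unit edit costs) and every difference is
   enumerated.

A self-dotplot (forward and reverse-complement word matches merged into
runs) is provided for visual confirmation of the repeat geometry.

Coordinates are 1-based inclusive in all reports; N bases never seed
matches.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import edlib

from .simulate import revcomp

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "-"}


# ---------------------------------------------------------------------------
# Insertion discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionCall:
    """An insertion in the alternate haplotype relative to the reference.

    ``breakpoint`` is the 1-based reference position immediately left of
    the inserted sequence (left-aligned single-coordinate convention).
    """

    breakpoint: int
    inserted_sequence: str

    @property
    def length(self) -> int:
        return len(self.inserted_sequence)


class NoAnchorChainError(ValueError):
    """The two sequences share no usable collinear anchor chain."""


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    """Positions (0-based) of k-mers occurring exactly once; N never seeds."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        counts[word] = -1 if word in counts else i
    return {w: p for w, p in counts.items() if p >= 0}


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing second coordinate
    (first coordinate already sorted ascending)."""
    tails: list[int] = []          # alt positions of chain tails
    tail_idx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (_, a) in enumerate(pairs):
        j = bisect.bisect_left(tails, a)
        if j == len(tails):
            tails.append(a)
            tail_idx.append(idx)
        else:
            tails[j] = a
            tail_idx[j] = idx
        parent[idx] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    idx = tail_idx[-1] if tail_idx else -1
    while idx >= 0:
        chain.append(pairs[idx])
        idx = parent[idx]
    return chain[::-1]


def call_insertion(
    reference: str,
    alternate: str,
    anchor_k: int = 31,
    min_chain_anchors: int = 10,
) -> list[InsertionCall]:
    """Find insertions in ``alternate`` relative to ``reference``.

    Returns a list of calls (empty if the sequences are collinear with
    no insertion); more than one element means multiple distinct gaps
    were found and all are reported.  Raises
    :class:`NoAnchorChainError` when no adequate anchor chain exists
    (effectively unrelated sequences).
    """
    if not reference or not alternate:
        raise ValueError("both haplotype sequences must be non-empty")
    ref_anchors = _unique_kmers(reference.upper(), anchor_k)
    alt_anchors = _unique_kmers(alternate.upper(), anchor_k)
    shared = [(rp, alt_anchors[w]) for w, rp in ref_anchors.items() if w in alt_anchors]
    shared.sort()
    chain = _lis_chain(shared)
    if len(chain) < min_chain_anchors:
        raise NoAnchorChainError(
            f"only {len(chain)} collinear anchors at k={anchor_k}; "
            "sequences appear unrelated"
        )

    calls: list[InsertionCall] = []
    for (r1, a1), (r2, a2) in zip(chain, chain[1:]):
        gap = (a2 - a1) - (r2 - r1)
        if gap > 0:
            breakpoint = r1 + anchor_k          # 1-based end of the left anchor
            start = a1 + anchor_k               # 0-based start of inserted segment
            inserted = alternate[start : start + gap]
            # left-align: an insertion whose tail matches the reference base
            # at the breakpoint has an equivalent representation one base left
            while breakpoint >= 1 and inserted[-1] == reference[breakpoint - 1]:
                inserted = reference[breakpoint - 1] + inserted[:-1]
                breakpoint -= 1
            calls.append(InsertionCall(breakpoint, inserted))
    if len(calls) > 1:
        logger.warning("multiple insertion gaps found (%d); all reported", len(calls))
    return calls


# ---------------------------------------------------------------------------
# Inverted-repeat detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvertedRepeatReport:
    """Geometry of an inverted repeat: arms, stem, loop, arm differences.

    Intervals are 1-based inclusive on the analyzed sequence, arm1
    before arm2.  ``arm_differences`` lists (position-on-arm1, type)
    pairs with type "substitution" or "single-base indel", from a unit
    cost global alignment of arm1 against the reverse complement of
    arm2.  ``stem_length`` is the arm1 length, ``loop_length`` the
    separation between the arms.
    """

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    stem_length: int
    loop_length: int
    arm_differences: tuple[tuple[int, str], ...]
    edit_distance: int
    trimmed: bool = False

    def to_dict(self) -> dict:
        return {
            "arm1_start": self.arm1[0], "arm1_end": self.arm1[1],
            "arm2_start": self.arm2[0], "arm2_end": self.arm2[1],
            "stem_length": self.stem_length, "loop_length": self.loop_length,
            "arm_differences": [list(d) for d in self.arm_differences],
            "edit_distance": self.edit_distance, "trimmed": self.trimmed,
        }


def _word_matches_vs_rc(seq: str, rc: str, word_size: int) -> list[tuple[int, int]]:
    """(i, j) word matches between seq and its reverse complement.

    Self-complementarity makes the match set mirror-symmetric
    ((i, j) <-> (L-k-j, L-k-i)); only the canonical half with the seq
    window left of its forward-strand partner (i < L - j - k) is kept,
    so each arm pairing appears once.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(rc) - word_size + 1):
        word = rc[j : j + word_size]
        if "N" not in word:
            index.setdefault(word, []).append(j)
    L = len(seq)
    matches = []
    for i in range(len(seq) - word_size + 1):
        word = seq[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            if i < L - j - word_size:
                matches.append((i, j))
    return matches


def _merge_diagonal_runs(matches: list[tuple[int, int]], word_size: int,
                         merge_gap: int) -> list[dict]:
    """Merge (i, j) word matches into maximal runs per diagonal i - j."""
    by_diag: dict[int, list[int]] = {}
    for i, j in matches:
        by_diag.setdefault(i - j, []).append(i)
    runs = []
    for diag, positions in by_diag.items():
        positions.sort()
        start = prev = positions[0]
        for i in positions[1:]:
            if i - prev > merge_gap:
                runs.append({"diag": diag, "i0": start, "i1": prev + word_size})
                start = i
            prev = i
        runs.append({"diag": diag, "i0": start, "i1": prev + word_size})
    return runs


def _chain_runs(runs: list[dict], band_width: int, max_gap: int) -> list[dict]:
    """Greedy collinear chaining of runs across nearby diagonals."""
    runs = sorted(runs, key=lambda r: (r["i0"], r["diag"]))
    used = [False] * len(runs)
    chains = []
    for s, run in enumerate(runs):
        if used[s]:
            continue
        used[s] = True
        chain = dict(run)
        while True:
            candidate = None
            for t in range(len(runs)):
                nxt = runs[t]
                if used[t]:
                    continue
                if nxt["i0"] < chain["i1"] - band_width:
                    continue
                if nxt["i0"] - chain["i1"] > max_gap:
                    continue
                if abs(nxt["diag"] - chain["diag"]) > band_width:
                    continue
                if candidate is None or nxt["i0"] < candidate[1]["i0"]:
                    candidate = (t, nxt)
            if candidate is None:
                break
            t, nxt = candidate
            used[t] = True
            chain["i1"] = max(chain["i1"], nxt["i1"])
            chain["diag"] = nxt["diag"]
            chain.setdefault("members", [run]).append(nxt)
        chain["runs"] = chain.pop("members", [run])
        chains.append(chain)
    return chains


def _resync_ok(seq: str, i: int, m: int, di: int, dm: int, lookahead: int = 8,
               min_checked: int = 4) -> bool:
    """Do the next ``lookahead`` outward base pairs complement-match?"""
    checked = 0
    for t in range(lookahead):
        ii, mm = i + di * t, m + dm * t
        if not (0 <= ii < len(seq) and 0 <= mm < len(seq)) or ii >= mm:
            break
        if seq[ii] != _COMPLEMENT.get(seq[mm], "-"):
            return False
        checked += 1
    return checked >= min_checked


def _extend_boundary(seq: str, i: int, m: int, di: int, dm: int,
                     stop) -> tuple[int, int]:
    """Extend a complementary pairing (seq[i] vs complement(seq[m]))
    stepwise, resynchronizing across isolated substitutions or
    single-base indels.  Returns final (i, m) one step past the last
    accepted pair."""
    while True:
        if stop(i, m):
            break
        if seq[i] == _COMPLEMENT.get(seq[m], "-"):
            i += di
            m += dm
            continue
        if _resync_ok(seq, i + di, m + dm, di, dm):          # substitution
            i += di
            m += dm
        elif _resync_ok(seq, i + di, m, di, dm):             # extra base on arm1 side
            i += di
        elif _resync_ok(seq, i, m + dm, di, dm):             # extra base on arm2 side
            m += dm
        else:
            break
    return i, m


def _enumerate_arm_differences(arm1: str, arm2: str) -> tuple[tuple[tuple[int, str], ...], int]:
    """Global unit-cost alignment of arm1 vs revcomp(arm2); differences
    as (1-based position on arm1, type)."""
    target = revcomp(arm2)
    result = edlib.align(arm1, target, mode="NW", task="path")
    cigar = result["cigar"] or ""
    differences: list[tuple[int, str]] = []
    pos = 0  # 0-based position on arm1
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            pos += n
        elif ch == "X":
            for t in range(n):
                differences.append((pos + t + 1, "substitution"))
            pos += n
        elif ch == "I":      # base in arm1 absent from revcomp(arm2)
            kind = "single-base indel" if n == 1 else "indel"
            for t in range(n):
                differences.append((pos + t + 1, kind))
            pos += n
        elif ch == "D":      # base in revcomp(arm2) absent from arm1
            kind = "single-base indel" if n == 1 else "indel"
            for _ in range(n):
                differences.append((pos + 1, kind))
        else:
            raise ValueError(f"unexpected alignment operation {ch!r}")
    return tuple(differences), int(result["editDistance"])


def find_inverted_repeat(
    sequence: str,
    min_stem: int = 500,
    band_width: int = 16,
    word_size: int = 15,
) -> InvertedRepeatReport | None:
    """Find the longest inverted repeat (stem >= ``min_stem``) in a sequence.

    Returns None when no qualifying repeat exists.  Overlapping arms
    (a near-perfect palindrome center) are trimmed to non-overlapping
    halves and flagged via ``trimmed``.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 2 * min_stem:
        raise ValueError("sequence shorter than twice the minimum stem")
    rc = revcomp(seq)
    matches = _word_matches_vs_rc(seq, rc, word_size)
    if not matches:
        return None
    runs = _merge_diagonal_runs(matches, word_size, merge_gap=3 * word_size)
    chains = _chain_runs(runs, band_width, max_gap=4 * word_size + band_width)

    candidates = []
    for chain in chains:
        i0 = min(r["i0"] for r in chain["runs"])
        i1 = max(r["i1"] for r in chain["runs"])
        j0 = min(r["i0"] - r["diag"] for r in chain["runs"])
        j1 = max(r["i1"] - r["diag"] for r in chain["runs"])
        m0, m1 = L - j1, L - j0      # arm2 on the forward strand
        if i0 >= m0:                 # symmetric twin (arm order reversed)
            continue
        candidates.append([i0, i1, m0, m1])
    if not candidates:
        return None

    polished = []
    for i0, i1, m0, m1 in candidates:
        # outer boundary: left end of arm1 pairs with right end of arm2
        i0n, m1n = _extend_boundary(
            seq, i0 - 1, m1, di=-1, dm=+1,
            stop=lambda i, m: i < 0 or m >= L,
        )
        i0, m1 = i0n + 1, m1n
        # inner boundary: right end of arm1 pairs with left end of arm2
        i1n, m0n = _extend_boundary(
            seq, i1, m0 - 1, di=+1, dm=-1,
            stop=lambda i, m: i >= m,
        )
        i1, m0 = i1n, m0n + 1
        trimmed = False
        if i1 > m0:                  # arms ran into each other: split evenly
            mid_excess = i1 - m0
            i1 -= (mid_excess + 1) // 2
            m0 += mid_excess // 2
            trimmed = True
        polished.append((i0, i1, m0, m1, trimmed))

    polished = [c for c in polished if c[1] - c[0] >= min_stem]
    if not polished:
        return None
    i0, i1, m0, m1, trimmed = max(polished, key=lambda c: (c[1] - c[0], -c[0]))

    differences, distance = _enumerate_arm_differences(seq[i0:i1], seq[m0:m1])
    return InvertedRepeatReport(
        arm1=(i0 + 1, i1),
        arm2=(m0 + 1, m1),
        stem_length=i1 - i0,
        loop_length=m0 - i1,
        arm_differences=differences,
        edit_distance=distance,
        trimmed=trimmed,
    )


# ---------------------------------------------------------------------------
# Self-dotplot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotplotRun:
    """A merged word-match run; 1-based starts, length in bases.

    Forward runs march down the main-diagonal direction ((x, y) ->
    (x+1, y+1)); reverse-complement runs march anti-diagonally ((x, y)
    -> (x+1, y-1)), with ``y_start`` the y of the first (leftmost) x.
    """

    x_start: int
    y_start: int
    length: int
    orientation: str  # "forward" or "reverse"


@dataclass
class DotplotMatchSet:
    sequence_length: int
    word_size: int
    runs: list[DotplotRun] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("x_start\ty_start\tlength\torientation\n")
            for run in self.runs:
                fh.write(f"{run.x_start}\t{run.y_start}\t{run.length}\t{run.orientation}\n")


def self_dotplot(sequence: str, word_size: int = 15, step: int = 1) -> DotplotMatchSet:
    """All exact self word matches, forward and reverse-complement.

    Matches are merged into diagonal (forward) and anti-diagonal
    (reverse) runs; the forward main diagonal is always present.
    """
    if word_size < 4:
        raise ValueError("word_size must be at least 4")
    seq = sequence.upper()
    L = len(seq)

    index: dict[str, list[int]] = {}
    for j in range(0, L - word_size + 1):
        word = seq[j : j + word_size]
        if "N" not in word:
            index.setdefault(word, []).append(j)

    forward: list[tuple[int, int]] = []
    for i in range(0, L - word_size + 1, step):
        word = seq[i : i + word_size]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            forward.append((i, j))

    rc = revcomp(seq)
    rc_index: dict[str, list[int]] = {}
    for j in range(0, len(rc) - word_size + 1):
        word = rc[j : j + word_size]
        if "N" not in word:
            rc_index.setdefault(word, []).append(j)
    reverse: list[tuple[int, int]] = []
    for i in range(0, L - word_size + 1, step):
        word = seq[i : i + word_size]
        if "N" in word:
            continue
        for j in rc_index.get(word, ()):
            reverse.append((i, L - j - word_size))  # y = forward-strand start

    runs: list[DotplotRun] = []
    for diag_runs in _merge_diagonal_runs(forward, word_size, merge_gap=step):
        i0, i1, diag = diag_runs["i0"], diag_runs["i1"], diag_runs["diag"]
        runs.append(DotplotRun(i0 + 1, i0 - diag + 1, i1 - i0, "forward"))

    # reverse matches: along a run, x increases while y decreases (x + y const)
    by_anti: dict[int, list[int]] = {}
    for x, y in reverse:
        by_anti.setdefault(x + y, []).append(x)
    for anti, xs in by_anti.items():
        xs.sort()
        start = prev = xs[0]
        for x in xs[1:] + [None]:
            if x is None or x - prev > step:
                runs.append(DotplotRun(start + 1, anti - start + 1,
                                       prev - start + word_size, "reverse"))
                if x is not None:
                    start = x
            if x is not None:
                prev = x

    return DotplotMatchSet(sequence_length=L, word_size=word_size, runs=runs)
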