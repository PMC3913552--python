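"""Substring matching with bounded substitutions.

The screen and the in-silico PCR both need every position at which a short
pattern matches a longer sequence with at most ``max_mismatch`` base
substitutions.  ``N`` never matches anything (including another ``N``): an
ambiguous base can neither support an anchor hit nor a primer site.

The production matcher is vectorised over all window positions with numpy;
tests compare it against a naive per-position scan.
"""

from __future__ import annotations

import numpy as np

_N = ord("N")


def _to_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def match_positions(sequence: str, pattern: str, max_mismatch: int = 0) -> list[int]:
    """0-based start positions where ``pattern`` matches within ``sequence``.

    A position matches when at most ``max_mismatch`` of the aligned bases
    disagree; an ``N`` on either side always counts as a disagreement.
    """
    n, m = len(sequence), len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if n < m:
        return []
    if max_mismatch == 0 and "N" not in pattern:
        # str.find is far faster than windowed comparison for exact search;
        # an N in the sequence can never lie inside a hit (pattern is N-free).
        out, i = [], sequence.find(pattern)
        while i != -1:
            out.append(i)
            i = sequence.find(pattern, i + 1)
        return out
    seq = _to_bytes(sequence)
    pat = _to_bytes(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    bad = (windows != pat) | (windows == _N) | (pat == _N)
    return np.nonzero(bad.sum(axis=1) <= max_mismatch)[0].tolist()


def contains(sequence: str, pattern: str, max_mismatch: int = 0) -> bool:
    """True if ``pattern`` occurs anywhere in ``sequence`` (see match_positions)."""
    if max_mismatch == 0 and "N" not in pattern:
        return pattern in sequence
    return bool(match_positions(sequence, pattern, max_mismatch))
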