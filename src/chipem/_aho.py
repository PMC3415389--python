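"""Aho–Corasick multi-pattern string matching.

Used to locate every occurrence of the member k-mers of a k-mer equivalence
class inside a genomic region in a single pass.  Patterns carry arbitrary
payloads; duplicate patterns accumulate multiple payloads.
"""

from __future__ import annotations

from collections import deque
from typing import Any, Iterable, Iterator


class AhoCorasick:
    """Deterministic automaton over the patterns added before ``build()``."""

    def __init__(self) -> None:
        # node: dict char -> next state; parallel arrays for fail/output
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[tuple[int, Any]]] = [[]]  # (pattern length, payload)
        self._built = False

    def add(self, pattern: str, payload: Any = None) -> None:
        if self._built:
            raise RuntimeError("cannot add patterns after build()")
        if not pattern:
            raise ValueError("empty pattern")
        state = 0
        for ch in pattern:
            nxt = self._goto[state].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
                self._goto[state][ch] = nxt
            state = nxt
        self._out[state].append((len(pattern), payload))

    def build(self) -> "AhoCorasick":
        queue: deque[int] = deque()
        for state in self._goto[0].values():
            self._fail[state] = 0
            queue.append(state)
        while queue:
            s = queue.popleft()
            for ch, nxt in self._goto[s].items():
                queue.append(nxt)
                f = self._fail[s]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]
        self._built = True
        return self

    def iter_matches(self, text: str) -> Iterator[tuple[int, Any]]:
        """Yield ``(start, payload)`` for every pattern occurrence in text."""
        if not self._built:
            raise RuntimeError("build() must be called before matching")
        state = 0
        goto, fail, out = self._goto, self._fail, self._out
        for i, ch in enumerate(text):
            while state and ch not in goto[state]:
                state = fail[state]
            state = goto[state].get(ch, 0)
            for length, payload in out[state]:
                yield i - length + 1, payload


def build_automaton(patterns: Iterable[tuple[str, Any]]) -> AhoCorasick:
    ac = AhoCorasick()
    for pattern, payload in patterns:
        ac.add(pattern, payload)
    return ac.build()
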