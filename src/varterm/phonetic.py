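"""Classic Metaphone phonetic encoding (Philips, 1990).

Maps English words to a consonant-skeleton code so that words that sound
alike share a code even when spelled differently — the second leg, next to
edit distance, of fuzzy token matching. Latin/Greek digraph spellings common
in medicine (``haemorrhage``/``hemorrhage``, ``oedema``/``edema``) encode
identically because non-initial vowels are dropped.

This is a from-scratch implementation of the published rule set. Codes are
compared only for equality; their exact spelling is an implementation detail.
"""

from __future__ import annotations

_VOWELS = "AEIOU"


def _is_vowel(word: str, i: int) -> bool:
    return 0 <= i < len(word) and word[i] in _VOWELS


def phonetic_code(token: str) -> str:
    """Return the Metaphone code of ``token``.

    Hyphens are stripped first; a token with no alphabetic characters yields
    the empty code, which by contract matches nothing.
    """
    word = "".join(ch for ch in token.upper() if ch.isalpha())
    if not word:
        return ""

    # initial-letter exceptions
    for prefix, repl in (("AE", "E"), ("GN", "N"), ("KN", "N"), ("PN", "N"),
                         ("WR", "R"), ("X", "S"), ("WH", "W")):
        if word.startswith(prefix):
            word = repl + word[len(prefix):]
            break

    out: list[str] = []
    i = 0
    n = len(word)
    while i < n:
        ch = word[i]
        # drop duplicate adjacent letters except C
        if ch != "C" and i > 0 and word[i - 1] == ch:
            i += 1
            continue
        nxt = word[i + 1] if i + 1 < n else ""
        nxt2 = word[i + 2] if i + 2 < n else ""

        if ch in _VOWELS:
            if i == 0:
                out.append(ch)
        elif ch == "B":
            if not (i == n - 1 and i > 0 and word[i - 1] == "M"):
                out.append("B")
        elif ch == "C":
            if nxt == "I" and nxt2 == "A":
                out.append("X")
            elif nxt == "H":
                if i > 0 and word[i - 1] == "S":
                    out.append("K")
                else:
                    out.append("X")
                i += 1
            elif nxt in "IEY":
                if not (i > 0 and word[i - 1] == "S"):
                    out.append("S")
            else:
                out.append("K")
        elif ch == "D":
            if nxt == "G" and nxt2 in "EIY":
                out.append("J")
                i += 1
            else:
                out.append("T")
        elif ch == "G":
            if nxt == "H":
                if not (i + 2 >= n or _is_vowel(word, i + 2)):
                    pass  # silent GH
                elif i + 1 == n - 1:
                    pass  # final GH: silent (rough -> RF handled below is skipped)
                else:
                    out.append("K")
                i += 1
            elif nxt == "N":
                pass  # GN(ED): silent G
            elif nxt in "IEY":
                out.append("J")
            else:
                out.append("K")
        elif ch == "F":
            out.append("F")
        elif ch == "H":
            if _is_vowel(word, i - 1) and not _is_vowel(word, i + 1):
                pass  # silent
            else:
                out.append("H")
        elif ch == "J":
            out.append("J")
        elif ch == "K":
            if not (i > 0 and word[i - 1] == "C"):
                out.append("K")
        elif ch in "LMNR":
            out.append(ch)
        elif ch == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif ch == "Q":
            out.append("K")
        elif ch == "S":
            if nxt == "H":
                out.append("X")
                i += 1
            elif nxt == "I" and nxt2 in "OA":
                out.append("X")
            else:
                out.append("S")
        elif ch == "T":
            if nxt == "I" and nxt2 in "OA":
                out.append("X")
            elif nxt == "H":
                out.append("0")
                i += 1
            elif nxt == "C" and nxt2 == "H":
                pass  # TCH -> CH
            else:
                out.append("T")
        elif ch == "V":
            out.append("F")
        elif ch == "W":
            if _is_vowel(word, i + 1):
                out.append("W")
        elif ch == "X":
            out.append("KS")
        elif ch == "Y":
            if _is_vowel(word, i + 1):
                out.append("Y")
        elif ch == "Z":
            out.append("S")
        i += 1

    return "".join(out)
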