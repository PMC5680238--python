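"""Independent brute-force oracle for isomiR interpretation.

Exhaustively enumerates every (mature, 5' offset) interpretation of a
read with naive per-base loops, scores each with the ordered
minimal-edit key, and returns the winner(s).  Written without reference
to the package's classifier internals so the two can disagree.
"""

from __future__ import annotations


def oracle_interpretations(read, ref, max_off5=3, max_del3=5, max_add3=5, max_subs=2):
    """All valid interpretations as (key, mature, off5, off3, subs, tail)."""
    results = []
    for m in ref.matures:
        hp = ref.hairpins[m.hairpin_id].sequence
        for off5 in range(-max_off5, max_off5 + 1):
            s = m.start + off5
            if s < 0:
                continue
            off3 = s + len(read) - m.end
            if off3 < -max_del3 or off3 > max_add3:
                continue
            body = len(read) - (off3 if off3 > 0 else 0)
            if body <= 0 or s + body > len(hp):
                continue
            subs = []
            bad = False
            for i in range(body):
                if read[i] != hp[s + i]:
                    if off5 < 0 and i < -off5:
                        bad = True  # 5' extension must be templated exactly
                        break
                    subs.append((i, hp[s + i], read[i]))
            if bad or len(subs) > max_subs:
                continue
            tail = ""
            if off3 > 0:
                t = 0
                while (
                    t < off3
                    and m.end + t < len(hp)
                    and read[body + t] == hp[m.end + t]
                ):
                    t += 1
                tail = read[body + t :]
            key = (len(subs), abs(off5) + abs(off3), len(tail), abs(off5), m.name, off5, off3)
            results.append((key, m.name, off5, off3, tuple(subs), tail))
    return results


def oracle_category(off5, off3, n_subs):
    changed = (off5 != 0) + (off3 != 0) + (n_subs > 0)
    if changed == 0:
        return "canonical"
    if changed >= 2:
        return "mixed"
    if n_subs:
        return "substitution"
    if off5 > 0:
        return "del5p"
    if off5 < 0:
        return "add5p"
    if off3 < 0:
        return "del3p"
    return "add3p"


def oracle_best(read, ref, **limits):
    """Winning interpretation or None; dict with category/offsets/tail."""
    results = oracle_interpretations(read, ref, **limits)
    if not results:
        return None
    key, name, off5, off3, subs, tail = min(results)
    return {
        "mature": name,
        "offset5": off5,
        "offset3": off3,
        "substitutions": subs,
        "tail": tail,
        "category": oracle_category(off5, off3, len(subs)),
    }
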