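"""Independent brute-force oracles shared by the test modules."""

CORE_START = 2
CORE_END = 13


def brute_force_scan(target: str, mirna: str, max_score: float):
    """Per-window complementarity scoring with explicit loops.

    Kept deliberately naive and independent of the vectorised scanner it
    checks: antiparallel pairing, mismatch 1.0, G:U wobble 0.5, penalties
    doubled at miRNA positions 2-13 from the 5' end.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(mirna)
    out = []
    for start in range(len(target) - L + 1):
        window = target[start : start + L]
        score = 0.0
        mism = wob = 0
        for k in range(1, L + 1):  # miRNA position from the 5' end
            m = mirna[k - 1]
            t = window[L - k]  # antiparallel pairing partner
            if t == comp[m]:
                pen = 0.0
            elif (m == "G" and t == "T") or (m == "T" and t == "G"):
                pen = 0.5
                wob += 1
            else:
                pen = 1.0
                mism += 1
            if CORE_START <= k <= CORE_END:
                pen *= 2
            score += pen
        if score <= max_score:
            out.append((start + 1, start + L, mism, wob, score))
    out.sort(key=lambda x: (x[4], x[0]))
    return out
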