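"""Independent brute-force oracles used by the tests.

Deliberately written with plain loops / textbook dynamic programming,
separate from the library's implementations, so agreement is meaningful.
"""

from itertools import product

import numpy as np

# The seven-group reduced amino-acid alphabet, written out residue by residue
# (independent of the implementation's group-string construction).
GROUP_LOOKUP = {
    "A": "1", "G": "1", "V": "1",
    "I": "2", "L": "2", "F": "2", "P": "2",
    "Y": "3", "M": "3", "T": "3", "S": "3",
    "H": "4", "N": "4", "Q": "4", "W": "4",
    "R": "5", "K": "5",
    "D": "6", "E": "6",
    "C": "7",
}


def kmer_block_oracle(symbols: str, k: int, alphabet: str) -> np.ndarray:
    """Sliding-window k-mer counter with an explicit dict and loops."""
    counts = {"".join(w): 0 for w in product(alphabet, repeat=k)}
    total = 0
    for i in range(len(symbols) - k + 1):
        window = symbols[i:i + k]
        if window in counts:
            counts[window] += 1
            total += 1
    vec = np.array([counts["".join(w)] for w in product(alphabet, repeat=k)],
                   dtype=float)
    return vec / total if total else vec


def encode_oracle(sequence: str, structure, molecule: str, scheme_name: str) -> np.ndarray:
    """Full encoder re-implemented from the coding-scheme definition."""
    if molecule == "protein":
        symbols = "".join(GROUP_LOOKUP.get(c, "?") for c in sequence.upper())
        alphabet, kmax, salpha = "1234567", 3, "HEC"
        struct_symbols = structure.upper() if structure else None
    else:
        symbols = "".join(
            c if c in "ACGU" else ("U" if c == "T" else "?")
            for c in sequence.upper()
        )
        alphabet, kmax, salpha = "ACGU", 4, "UP"
        struct_symbols = (
            structure.replace(".", "U").replace("(", "P").replace(")", "P")
            if structure else None
        )
    ks = [kmax] if scheme_name == "ctf" else list(range(1, kmax + 1))
    blocks = [kmer_block_oracle(symbols, k, alphabet) for k in ks]
    if scheme_name == "isctf":
        blocks += [kmer_block_oracle(struct_symbols, k, salpha)
                   for k in range(1, kmax + 1)]
    return np.concatenate(blocks)


def lcs_identity_oracle(a: str, b: str) -> float:
    """LCS via the classic O(nm) table, over min sequence length."""
    n, m = len(a), len(b)
    prev = np.zeros(m + 1, dtype=np.int32)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=np.int32)
        cur[0] = 0
        match = (bb == ord(a[i - 1]))
        # cur[j] = max(prev[j], cur[j-1], prev[j-1] + match); the cur[j-1]
        # dependency is a running maximum, i.e. a cumulative max
        cand = prev[:-1] + match
        np.maximum(cand, prev[1:], out=cand)
        np.maximum.accumulate(cand, out=cand)
        cur[1:] = cand
        prev = cur
    return float(prev[m]) / min(n, m)


def lcs_identity_slow(a: str, b: str) -> float:
    """Pure-python LCS for tiny strings (the small-instance oracle)."""
    n, m = len(a), len(b)
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
            else:
                table[i][j] = max(table[i - 1][j], table[i][j - 1])
    return table[n][m] / min(n, m)


def metrics_oracle(labels, scores, threshold=0.5):
    """All six metrics by explicit loops and the Mann-Whitney form of AUC."""
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        predicted = s >= threshold
        if y == 1 and predicted:
            tp += 1
        elif y == 1:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    import math

    def div(a, b):
        return a / b if b else math.nan

    total = tp + tn + fp + fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    pos_scores = [s for y, s in zip(labels, scores) if y == 1]
    neg_scores = [s for y, s in zip(labels, scores) if y == 0]
    if pos_scores and neg_scores:
        wins = 0.0
        for sp_ in pos_scores:
            for sn_ in neg_scores:
                if sp_ > sn_:
                    wins += 1.0
                elif sp_ == sn_:
                    wins += 0.5
        auc = wins / (len(pos_scores) * len(neg_scores))
    else:
        auc = math.nan
    return {
        "acc": div(tp + tn, total),
        "sn": div(tp, tp + fn),
        "sp": div(tn, tn + fp),
        "pre": div(tp, tp + fp),
        "mcc": (tp * tn - fp * fn) / den if den else math.nan,
        "auc": auc,
    }
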