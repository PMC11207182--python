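"""Independent brute-force reference implementations used only by tests.

Each function recomputes an encoding or metric by direct counting /
enumeration, written as naively as possible so it shares no code path with
the package implementation.
"""

import itertools
import math

NTS = "ACGU"
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}
NCP = {"A": [1, 1, 1], "C": [0, 1, 0], "G": [1, 0, 0], "U": [0, 0, 1]}
COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


def all_kmers(k):
    return ["".join(t) for t in itertools.product(NTS, repeat=k)]


def binary(seq):
    out = []
    for c in seq:
        out.extend(1.0 if c == n else 0.0 for n in NTS)
    return out


def enac(seq, window=5):
    out = []
    for j in range(len(seq) - window + 1):
        sub = seq[j : j + window]
        out.extend(sub.count(n) / window for n in NTS)
    return out


def ncp(seq):
    out = []
    for c in seq:
        out.extend(float(x) for x in NCP[c])
    return out


def anf(seq):
    return [seq[: i + 1].count(seq[i]) / (i + 1) for i in range(len(seq))]


def kmer_freq(seq, k):
    n = len(seq) - k + 1
    return [sum(seq[i : i + k] == m for i in range(n)) / n for m in all_kmers(k)]


def eiip(seq):
    f = kmer_freq(seq, 3)
    return [
        (EIIP[m[0]] + EIIP[m[1]] + EIIP[m[2]]) * fv
        for m, fv in zip(all_kmers(3), f)
    ]


def pse_eiip(seq):
    return [v / 3.0 for v in eiip(seq)]


def gapped_pairs(seq, k):
    slots = len(seq) - k - 1
    out = []
    for pair in all_kmers(2):
        cnt = sum(
            seq[i] == pair[0] and seq[i + k + 1] == pair[1] for i in range(slots)
        )
        out.append(cnt / slots)
    return out


def cksnap(seq, gaps=(0, 1, 2, 3, 4, 5)):
    out = []
    for k in gaps:
        out.extend(gapped_pairs(seq, k))
    return out


def nps(seq, d_max=3):
    out = []
    for k in range(d_max + 1):
        out.extend(gapped_pairs(seq, k))
    return out


def rckmer(seq, k=2):
    def canon(m):
        rc = "".join(COMP[c] for c in reversed(m))
        return min(m, rc)

    reps = sorted({canon(m) for m in all_kmers(k)})
    n = len(seq) - k + 1
    counts = {r: 0 for r in reps}
    for i in range(n):
        counts[canon(seq[i : i + k])] += 1
    return [counts[r] / n for r in reps]


def ctd(seq):
    L = len(seq)
    comp = [seq.count(n) / L for n in NTS]
    pairs = [("A", "C"), ("A", "G"), ("A", "U"), ("C", "G"), ("C", "U"), ("G", "U")]
    trans = []
    for x, y in pairs:
        cnt = sum(
            {seq[i], seq[i + 1]} == {x, y} for i in range(L - 1)
        )
        trans.append(cnt / (L - 1))
    dist = []
    for n in NTS:
        where = [i + 1 for i, c in enumerate(seq) if c == n]
        if not where:
            dist.extend([0.0] * 5)
        else:
            cnt = len(where)
            for q in (None, 0.25, 0.5, 0.75, "last"):
                if q is None:
                    dist.append(where[0] / L)
                elif q == "last":
                    dist.append(where[-1] / L)
                else:
                    dist.append(where[max(1, math.ceil(q * cnt)) - 1] / L)
    return comp + trans + dist


def ncp_nd(seq):
    out = []
    for i, c in enumerate(seq):
        out.extend(float(x) for x in NCP[c])
        out.append(seq[: i + 1].count(c) / (i + 1))
    return out


def bpb_matrices(seqs, pc):
    L = len(seqs[0])
    mat = {n: [0.0] * L for n in NTS}
    for s in seqs:
        for i, c in enumerate(s):
            mat[c][i] += 1
    for n in NTS:
        for i in range(L):
            mat[n][i] = (mat[n][i] + pc) / (len(seqs) + 4 * pc)
    return mat


def bpb(seq, pos_seqs, neg_seqs, pc):
    pmat = bpb_matrices(pos_seqs, pc)
    nmat = bpb_matrices(neg_seqs, pc)
    return [pmat[c][i] for i, c in enumerate(seq)] + [
        nmat[c][i] for i, c in enumerate(seq)
    ]


def npps(seq, pos_seqs, neg_seqs, k, pc):
    L = len(seq)

    def pair_mat(seqs):
        slots = L - k - 1
        mat = {p: [0.0] * slots for p in all_kmers(2)}
        for s in seqs:
            for i in range(slots):
                mat[s[i] + s[i + k + 1]][i] += 1
        for p in all_kmers(2):
            for i in range(slots):
                mat[p][i] = (mat[p][i] + pc) / (len(seqs) + 16 * pc)
        return mat

    fs_p, fs_n = bpb_matrices(pos_seqs, pc), bpb_matrices(neg_seqs, pc)
    fd_p, fd_n = pair_mat(pos_seqs), pair_mat(neg_seqs)
    out = []
    for i in range(L - k - 1):
        pair = seq[i] + seq[i + k + 1]
        second = seq[i + k + 1]
        p_plus = fd_p[pair][i] / fs_p[second][i + k + 1]
        p_minus = fd_n[pair][i] / fs_n[second][i + k + 1]
        out.append(p_plus - p_minus)
    return out


def pseknc(seq, props, k=2, lam=2, w=0.1):
    L = len(seq)
    names = sorted(props)
    f = kmer_freq(seq, k)
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j - 1):
            d1, d2 = seq[i : i + 2], seq[i + j : i + j + 2]
            total += sum((props[p][d1] - props[p][d2]) ** 2 for p in names) / len(
                names
            )
        thetas.append(total / (L - j - 1))
    denom = sum(f) + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


def w2v_mean(seq, table, token_k, dim):
    toks = [seq[i : i + token_k] for i in range(len(seq) - token_k + 1)]
    acc = [0.0] * dim
    for t in toks:
        vec = table.get(t, [0.0] * dim)
        for j in range(dim):
            acc[j] += float(vec[j])
    return [a / len(toks) for a in acc]


# ---- metrics -------------------------------------------------------------

def metric_summary(tp, fp, tn, fn):
    def div(a, b):
        return a / b if b else 0.0

    mcc_den = math.sqrt((tn + fn) * (tp + fp) * (tn + fp) * (tp + fn))
    return {
        "SEN": div(tp, tp + fn),
        "SPE": div(tn, tn + fp),
        "PRE": div(tp, tp + fp),
        "ACC": div(tp + tn, tp + fp + tn + fn),
        "MCC": div(tp * tn - fp * fn, mcc_den),
    }


def auc_all_pairs(labels, scores):
    pos = [s for lab, s in zip(labels, scores) if lab == 1]
    neg = [s for lab, s in zip(labels, scores) if lab == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
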