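"""The 18 RNA sequence feature encodings.

Every encoder maps a validated length-L window over {A,C,G,U} to a fixed,
named numeric vector. Fifteen encoders are stateless; three are
data-dependent and must be fitted first:

* BPB  -- bi-profile Bayes positional likelihood profiles, fitted on
  labelled positive/negative training sequences;
* NPPS -- position-specific single-nucleotide and k-spaced pair profiles,
  also class-conditional;
* W2V  -- skip-gram embeddings of overlapping 3-mer tokens, fitted on an
  (unlabelled) corpus.

Feature ordering conventions: k-mer-indexed vectors are lexicographic over
A < C < G < U; positional blocks run 5'->3'. Dimensions are derived from L,
never hard-coded to 41.

Fit-dependent encoders must be fitted inside each cross-validation training
fold only; the model-building layer enforces this.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np

from .seqio import ALPHABET
from .skipgram import train_skipgram

_IDX = {c: i for i, c in enumerate(ALPHABET)}

#: Electron-ion interaction pseudopotentials (dimensionless) per nucleotide.
EIIP_TABLE = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335}

#: Nucleotide chemical properties: (ring structure, functional group, H-bond).
NCP_TABLE = {"A": (1, 1, 1), "C": (0, 1, 0), "G": (1, 0, 0), "U": (0, 0, 1)}

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class EncoderError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureVector:
    """A named, fixed-dimension numeric encoding of one sequence."""

    values: np.ndarray
    names: tuple[str, ...]
    encoder_id: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != len(self.names):
            raise EncoderError(
                f"{self.encoder_id}: {values.size} values vs {len(self.names)} names"
            )
        if not np.all(np.isfinite(values)):
            raise EncoderError(f"{self.encoder_id}: non-finite feature values")

    def __len__(self) -> int:
        return self.values.size


def kmer_list(k: int) -> list[str]:
    """All k-mers over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def reverse_complement(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def canonical_kmer(s: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(s)
    return s if s <= rc else rc


def canonical_kmer_list(k: int) -> list[str]:
    """Distinct canonical k-mers, in lexicographic order (10 for k=2)."""
    return sorted({canonical_kmer(m) for m in kmer_list(k)})


# ---------------------------------------------------------------------------
# stateless encoders
# ---------------------------------------------------------------------------

def binary_encode(seq: str) -> FeatureVector:
    """Per-position one-hot over (A,C,G,U), concatenated 5'->3' (4L dims)."""
    L = len(seq)
    v = np.zeros(4 * L)
    for i, c in enumerate(seq):
        v[4 * i + _IDX[c]] = 1.0
    names = tuple(f"pos{i + 1}_{n}" for i in range(L) for n in ALPHABET)
    return FeatureVector(v, names, "Binary")


def enac_encode(seq: str, window: int = 5) -> FeatureVector:
    """Sliding-window nucleotide composition, 4*(L-window+1) dims."""
    L = len(seq)
    if window > L:
        raise EncoderError(f"ENAC window {window} > sequence length {L}")
    nwin = L - window + 1
    v = np.zeros(4 * nwin)
    for j in range(nwin):
        sub = seq[j : j + window]
        for c in sub:
            v[4 * j + _IDX[c]] += 1.0
    v /= window
    names = tuple(f"win{j + 1}_{n}" for j in range(nwin) for n in ALPHABET)
    return FeatureVector(v, names, "ENAC", {"window": window})


def ncp_encode(seq: str) -> FeatureVector:
    """Ring-structure / functional-group / hydrogen-bond triples (3L dims)."""
    v = np.array([x for c in seq for x in NCP_TABLE[c]], dtype=float)
    names = tuple(
        f"pos{i + 1}_{p}" for i in range(len(seq)) for p in ("ring", "func", "hbond")
    )
    return FeatureVector(v, names, "NCP")


def _cumulative_density(seq: str) -> np.ndarray:
    """d_i = (occurrences of seq[i] among positions 1..i) / i."""
    L = len(seq)
    counts = {c: 0 for c in ALPHABET}
    out = np.empty(L)
    for i, c in enumerate(seq):
        counts[c] += 1
        out[i] = counts[c] / (i + 1)
    return out


def anf_encode(seq: str) -> FeatureVector:
    """Accumulated nucleotide frequency (L dims)."""
    v = _cumulative_density(seq)
    names = tuple(f"pos{i + 1}" for i in range(len(seq)))
    return FeatureVector(v, names, "ANF")


def _kmer_freqs(seq: str, k: int) -> np.ndarray:
    L = len(seq)
    if k > L:
        raise EncoderError(f"k={k} > sequence length {L}")
    order = {m: i for i, m in enumerate(kmer_list(k))}
    v = np.zeros(4**k)
    for i in range(L - k + 1):
        v[order[seq[i : i + k]]] += 1.0
    return v / (L - k + 1)


def eiip_encode(seq: str) -> FeatureVector:
    """Summed trinucleotide pseudopotential x trinucleotide frequency (64 dims)."""
    if len(seq) < 3:
        raise EncoderError("EIIP needs L >= 3")
    tris = kmer_list(3)
    f = _kmer_freqs(seq, 3)
    energy = np.array([sum(EIIP_TABLE[c] for c in t) for t in tris])
    return FeatureVector(energy * f, tuple(f"EIIP_{t}" for t in tris), "EIIP")


def pse_eiip_encode(seq: str) -> FeatureVector:
    """Mean trinucleotide pseudopotential x frequency (64 dims); = EIIP / 3."""
    fv = eiip_encode(seq)
    return FeatureVector(
        fv.values / 3.0, tuple(f"PseEIIP_{t}" for t in kmer_list(3)), "PseEIIP"
    )


def dnc_encode(seq: str) -> FeatureVector:
    """Dinucleotide composition over L-1 adjacent pairs (16 dims, sums to 1)."""
    if len(seq) < 2:
        raise EncoderError("DNC needs L >= 2")
    return FeatureVector(
        _kmer_freqs(seq, 2), tuple(f"DNC_{m}" for m in kmer_list(2)), "DNC"
    )


def tnc_encode(seq: str) -> FeatureVector:
    """Trinucleotide composition over L-2 windows (64 dims, sums to 1)."""
    if len(seq) < 3:
        raise EncoderError("TNC needs L >= 3")
    return FeatureVector(
        _kmer_freqs(seq, 3), tuple(f"TNC_{m}" for m in kmer_list(3)), "TNC"
    )


def kmer_encode(seq: str, k: int = 4) -> FeatureVector:
    """k-mer composition (4^k dims, sums to 1)."""
    return FeatureVector(
        _kmer_freqs(seq, k), tuple(f"Kmer_{m}" for m in kmer_list(k)), "Kmer", {"k": k}
    )


def _gapped_pair_freqs(seq: str, k: int) -> np.ndarray:
    """Frequencies of the 16 ordered pairs (s_i, s_{i+k+1}) over L-k-1 slots."""
    L = len(seq)
    npairs = L - k - 1
    if npairs < 1:
        raise EncoderError(f"gap {k} too large for sequence length {L}")
    v = np.zeros(16)
    for i in range(npairs):
        v[4 * _IDX[seq[i]] + _IDX[seq[i + k + 1]]] += 1.0
    return v / npairs


def cksnap_encode(seq: str, gaps: Sequence[int] = (0, 1, 2, 3, 4, 5)) -> FeatureVector:
    """Composition of k-spaced nucleotide pairs, 16 features per gap."""
    L = len(seq)
    gaps = tuple(gaps)
    if max(gaps) > L - 2:
        raise EncoderError(f"max gap {max(gaps)} > L-2 = {L - 2}")
    blocks = [_gapped_pair_freqs(seq, k) for k in gaps]
    names = tuple(f"gap{k}_{m}" for k in gaps for m in kmer_list(2))
    return FeatureVector(np.concatenate(blocks), names, "CKSNAP", {"gaps": gaps})


def nps_encode(seq: str, d_max: int = 3) -> FeatureVector:
    """Nucleotide pair spectrum: gapped-pair frequencies for k = 0..d_max."""
    L = len(seq)
    if d_max > L - 2:
        raise EncoderError(f"d_max {d_max} > L-2 = {L - 2}")
    blocks = [_gapped_pair_freqs(seq, k) for k in range(d_max + 1)]
    names = tuple(
        f"k{k}_{m}" for k in range(d_max + 1) for m in kmer_list(2)
    )
    return FeatureVector(np.concatenate(blocks), names, "NPS", {"d_max": d_max})


def rckmer_encode(seq: str, k: int = 2) -> FeatureVector:
    """Reverse-complement-collapsed k-mer composition (10 dims for k=2)."""
    L = len(seq)
    if k > L:
        raise EncoderError(f"k={k} > sequence length {L}")
    canon = canonical_kmer_list(k)
    order = {m: i for i, m in enumerate(canon)}
    v = np.zeros(len(canon))
    for i in range(L - k + 1):
        v[order[canonical_kmer(seq[i : i + k])]] += 1.0
    v /= L - k + 1
    return FeatureVector(v, tuple(f"RCKmer_{m}" for m in canon), "RCKmer", {"k": k})


def ctd_encode(seq: str) -> FeatureVector:
    """Composition (4) + transition (6) + distribution (20) descriptors.

    Transitions are the six unordered distinct-nucleotide adjacent pairs,
    counted in either orientation over the L-1 adjacent positions.
    Distribution records, for each nucleotide, the 1-based positions of its
    first, 25%, 50%, 75% and last occurrence as fractions of L (0 if absent).
    """
    L = len(seq)
    if L < 2:
        raise EncoderError("CTD needs L >= 2")
    comp = np.array([seq.count(n) / L for n in ALPHABET])

    pairs = [("A", "C"), ("A", "G"), ("A", "U"), ("C", "G"), ("C", "U"), ("G", "U")]
    trans = np.zeros(6)
    for i in range(L - 1):
        a, b = seq[i], seq[i + 1]
        for j, (x, y) in enumerate(pairs):
            if (a, b) == (x, y) or (a, b) == (y, x):
                trans[j] += 1.0
    trans /= L - 1

    dist = []
    for n in ALPHABET:
        positions = [i + 1 for i, c in enumerate(seq) if c == n]
        if not positions:
            dist.extend([0.0] * 5)
            continue
        cnt = len(positions)
        picks = [
            positions[0],
            positions[max(0, int(np.ceil(0.25 * cnt)) - 1)],
            positions[max(0, int(np.ceil(0.50 * cnt)) - 1)],
            positions[max(0, int(np.ceil(0.75 * cnt)) - 1)],
            positions[-1],
        ]
        dist.extend(p / L for p in picks)

    names = (
        tuple(f"comp_{n}" for n in ALPHABET)
        + tuple(f"trans_{x}{y}" for x, y in pairs)
        + tuple(f"dist_{n}_{q}" for n in ALPHABET for q in ("first", "q25", "q50", "q75", "last"))
    )
    return FeatureVector(np.concatenate([comp, trans, np.array(dist)]), names, "CTD")


def ncp_nd_encode(seq: str) -> FeatureVector:
    """NCP triple + cumulative nucleotide density per position (4L dims)."""
    L = len(seq)
    dens = _cumulative_density(seq)
    v = np.empty(4 * L)
    for i, c in enumerate(seq):
        v[4 * i : 4 * i + 3] = NCP_TABLE[c]
        v[4 * i + 3] = dens[i]
    names = tuple(
        f"pos{i + 1}_{p}"
        for i in range(L)
        for p in ("ring", "func", "hbond", "density")
    )
    return FeatureVector(v, names, "NCP-ND")


# ---------------------------------------------------------------------------
# fit-dependent encoders: BPB, NPPS, W2V
# ---------------------------------------------------------------------------

def _position_profile(seqs: Sequence[str], L: int, pseudocount: float) -> np.ndarray:
    """4 x L matrix of smoothed per-position nucleotide probabilities."""
    counts = np.zeros((4, L))
    for s in seqs:
        for i, c in enumerate(s):
            counts[_IDX[c], i] += 1.0
    return (counts + pseudocount) / (len(seqs) + 4.0 * pseudocount)


@dataclass(frozen=True)
class BpbProfile:
    """Bi-profile Bayes positional likelihoods from both training classes."""

    pos_matrix: np.ndarray  # 4 x L
    neg_matrix: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.pos_matrix.shape[1]


def bpb_fit(
    pos_train: Sequence[str], neg_train: Sequence[str], pseudocount: float = 0.25
) -> BpbProfile:
    if not pos_train or not neg_train:
        raise EncoderError("BPB requires non-empty positive and negative sets")
    L = len(pos_train[0])
    for s in itertools.chain(pos_train, neg_train):
        if len(s) != L:
            raise EncoderError("BPB training sequences must share one length")
    return BpbProfile(
        _position_profile(pos_train, L, pseudocount),
        _position_profile(neg_train, L, pseudocount),
        pseudocount,
    )


def bpb_encode(seq: str, profile: BpbProfile) -> FeatureVector:
    """Concatenated positive then negative positional likelihoods (2L dims)."""
    L = len(seq)
    if L != profile.length:
        raise EncoderError(f"BPB profile fitted at L={profile.length}, got {L}")
    idx = [_IDX[c] for c in seq]
    cols = np.arange(L)
    v = np.concatenate([profile.pos_matrix[idx, cols], profile.neg_matrix[idx, cols]])
    names = tuple(f"p_pos{i + 1}" for i in range(L)) + tuple(
        f"n_pos{i + 1}" for i in range(L)
    )
    return FeatureVector(v, names, "BPB", {"pseudocount": profile.pseudocount})


def _pair_profile(
    seqs: Sequence[str], L: int, k: int, pseudocount: float
) -> np.ndarray:
    """16 x (L-k-1) matrix of smoothed positional k-spaced pair probabilities."""
    npos = L - k - 1
    counts = np.zeros((16, npos))
    for s in seqs:
        for i in range(npos):
            counts[4 * _IDX[s[i]] + _IDX[s[i + k + 1]], i] += 1.0
    return (counts + pseudocount) / (len(seqs) + 16.0 * pseudocount)


@dataclass(frozen=True)
class NppsProfile:
    """Class-conditional positional single-nucleotide and pair profiles."""

    fs_pos: np.ndarray  # 4 x L
    fs_neg: np.ndarray
    fd_pos: np.ndarray  # 16 x (L - k - 1)
    fd_neg: np.ndarray
    k: int
    pseudocount: float

    @property
    def length(self) -> int:
        return self.fs_pos.shape[1]


def npps_fit(
    pos_train: Sequence[str],
    neg_train: Sequence[str],
    k: int = 0,
    pseudocount: float = 0.25,
) -> NppsProfile:
    if not pos_train or not neg_train:
        raise EncoderError("NPPS requires non-empty positive and negative sets")
    L = len(pos_train[0])
    if L - k - 1 < 1:
        raise EncoderError(f"gap k={k} too large for L={L}")
    for s in itertools.chain(pos_train, neg_train):
        if len(s) != L:
            raise EncoderError("NPPS training sequences must share one length")
    return NppsProfile(
        _position_profile(pos_train, L, pseudocount),
        _position_profile(neg_train, L, pseudocount),
        _pair_profile(pos_train, L, k, pseudocount),
        _pair_profile(neg_train, L, k, pseudocount),
        k,
        pseudocount,
    )


def npps_encode(seq: str, profile: NppsProfile) -> FeatureVector:
    """Difference of class-conditional pair-vs-single ratios (L-k-1 dims).

    p_i = fd[pair at i] / fs[second member of the pair, position i+k+1];
    the output is p+ - p- elementwise.
    """
    L = len(seq)
    k = profile.k
    if L != profile.length:
        raise EncoderError(f"NPPS profile fitted at L={profile.length}, got {L}")
    npos = L - k - 1
    v = np.empty(npos)
    for i in range(npos):
        pair = 4 * _IDX[seq[i]] + _IDX[seq[i + k + 1]]
        second = _IDX[seq[i + k + 1]]
        fs_p = profile.fs_pos[second, i + k + 1]
        fs_n = profile.fs_neg[second, i + k + 1]
        if fs_p == 0.0 or fs_n == 0.0:
            raise EncoderError(
                "zero positional probability; refit with a positive pseudocount"
            )
        v[i] = profile.fd_pos[pair, i] / fs_p - profile.fd_neg[pair, i] / fs_n
    names = tuple(f"pair{i + 1}" for i in range(npos))
    return FeatureVector(v, names, "NPPS", {"k": k, "pseudocount": profile.pseudocount})


# --- PseKNC ---------------------------------------------------------------

def load_default_props() -> dict[str, dict[str, float]]:
    """Packaged synthetic standardized dinucleotide property table.

    The six properties are named after the usual RNA helical parameters
    (rise, roll, shift, slide, tilt, twist) but the packaged values are
    synthetic standardized placeholders, not measurements; substitute a
    measured table for physically meaningful correlation terms.
    """
    ref = resources.files("nmstack.data").joinpath(
        "rna_dinucleotide_props_synthetic.json"
    )
    return json.loads(ref.read_text())["properties"]


@dataclass(frozen=True)
class PseKncSpec:
    """Pseudo k-tuple nucleotide composition parameters.

    lam correlation tiers weighted by w are appended to the 4^k k-mer
    frequencies; property values are standardized (mean 0, sd 1) across the
    16 dinucleotides.
    """

    k: int = 2
    lam: int = 2
    w: float = 0.1
    props: dict[str, dict[str, float]] = field(default_factory=load_default_props)

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise EncoderError("PseKNC weight w must be positive")
        for name, table in self.props.items():
            vals = np.array([table[d] for d in kmer_list(2)])
            if abs(vals.mean()) > 1e-6 or abs(vals.std(ddof=0) - 1.0) > 1e-6:
                raise EncoderError(
                    f"property {name!r} not standardized over the 16 dinucleotides"
                )


def pseknc_encode(seq: str, spec: PseKncSpec | None = None) -> FeatureVector:
    """k-mer frequencies plus lam sequence-order correlation terms."""
    spec = spec or PseKncSpec()
    L = len(seq)
    if spec.lam >= L - 1:
        raise EncoderError(f"lam={spec.lam} must be < L-1 = {L - 1}")
    if L < spec.k:
        raise EncoderError(f"k={spec.k} > sequence length {L}")
    f = _kmer_freqs(seq, spec.k)
    prop_names = sorted(spec.props)
    ptab = {
        d: np.array([spec.props[p][d] for p in prop_names]) for d in kmer_list(2)
    }

    def theta_tier(j: int) -> float:
        total = 0.0
        for i in range(L - j - 1):
            a = ptab[seq[i : i + 2]]
            b = ptab[seq[i + j : i + j + 2]]
            total += float(np.mean((a - b) ** 2))
        return total / (L - j - 1)

    thetas = np.array([theta_tier(j) for j in range(1, spec.lam + 1)])
    denom = f.sum() + spec.w * thetas.sum()
    v = np.concatenate([f / denom, spec.w * thetas / denom])
    names = tuple(f"Kmer_{m}" for m in kmer_list(spec.k)) + tuple(
        f"theta{j}" for j in range(1, spec.lam + 1)
    )
    return FeatureVector(
        v, names, "PseKNC", {"k": spec.k, "lam": spec.lam, "w": spec.w}
    )


# --- W2V ------------------------------------------------------------------

def tokenize(seq: str, k: int = 3, stride: int = 1) -> list[str]:
    """Overlapping k-mer tokens, 5'->3'."""
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, stride)]


@dataclass(frozen=True)
class W2vModel:
    """A fitted skip-gram embedding table over k-mer tokens.

    Out-of-vocabulary tokens map to the zero vector; transform is
    deterministic given the table.
    """

    table: dict[str, np.ndarray]
    dim: int = 64
    token_k: int = 3
    stride: int = 1
    window: int = 5
    seed: int = 0
    pooling: str = "mean"


def w2v_fit(
    corpus: Sequence[str],
    dim: int = 64,
    token_k: int = 3,
    stride: int = 1,
    window: int = 5,
    epochs: int = 3,
    seed: int = 0,
    pooling: str = "mean",
) -> W2vModel:
    """Train skip-gram embeddings on k-mer token sentences from the corpus."""
    if not corpus:
        raise EncoderError("W2V requires a non-empty corpus")
    if pooling not in ("mean", "concat"):
        raise EncoderError(f"unknown pooling {pooling!r}")
    sentences = [tokenize(s, token_k, stride) for s in corpus]
    table = train_skipgram(sentences, dim=dim, window=window, epochs=epochs, seed=seed)
    return W2vModel(table, dim, token_k, stride, window, seed, pooling)


def w2v_encode(seq: str, model: W2vModel) -> FeatureVector:
    toks = tokenize(seq, model.token_k, model.stride)
    zero = np.zeros(model.dim)
    vecs = [model.table.get(t, zero) for t in toks]
    if model.pooling == "mean":
        v = np.mean(vecs, axis=0)
        names = tuple(f"w2v_{j}" for j in range(model.dim))
    else:
        v = np.concatenate(vecs)
        names = tuple(
            f"tok{i + 1}_w2v_{j}" for i in range(len(toks)) for j in range(model.dim)
        )
    return FeatureVector(
        v, names, "W2V", {"dim": model.dim, "pooling": model.pooling}
    )


# ---------------------------------------------------------------------------
# profile serialization (versioned JSON)
# ---------------------------------------------------------------------------

def profile_to_json(profile) -> str:
    if isinstance(profile, BpbProfile):
        payload = {
            "kind": "BPB",
            "version": 1,
            "pos_matrix": profile.pos_matrix.tolist(),
            "neg_matrix": profile.neg_matrix.tolist(),
            "pseudocount": profile.pseudocount,
        }
    elif isinstance(profile, NppsProfile):
        payload = {
            "kind": "NPPS",
            "version": 1,
            "fs_pos": profile.fs_pos.tolist(),
            "fs_neg": profile.fs_neg.tolist(),
            "fd_pos": profile.fd_pos.tolist(),
            "fd_neg": profile.fd_neg.tolist(),
            "k": profile.k,
            "pseudocount": profile.pseudocount,
        }
    elif isinstance(profile, W2vModel):
        payload = {
            "kind": "W2V",
            "version": 1,
            "table": {t: v.tolist() for t, v in profile.table.items()},
            "dim": profile.dim,
            "token_k": profile.token_k,
            "stride": profile.stride,
            "window": profile.window,
            "seed": profile.seed,
            "pooling": profile.pooling,
        }
    else:
        raise TypeError(f"unsupported profile type {type(profile)!r}")
    return json.dumps(payload)


def profile_from_json(text: str):
    data = json.loads(text)
    kind = data["kind"]
    if kind == "BPB":
        return BpbProfile(
            np.array(data["pos_matrix"]),
            np.array(data["neg_matrix"]),
            data["pseudocount"],
        )
    if kind == "NPPS":
        return NppsProfile(
            np.array(data["fs_pos"]),
            np.array(data["fs_neg"]),
            np.array(data["fd_pos"]),
            np.array(data["fd_neg"]),
            data["k"],
            data["pseudocount"],
        )
    if kind == "W2V":
        return W2vModel(
            {t: np.array(v) for t, v in data["table"].items()},
            data["dim"],
            data["token_k"],
            data["stride"],
            data["window"],
            data["seed"],
            data["pooling"],
        )
    raise ValueError(f"unknown profile kind {kind!r}")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderSpec:
    """Descriptor binding an encoder id to its transform/fit callables."""

    id: str
    requires_fit: bool
    default_params: dict
    _transform: Callable
    _fit: Optional[Callable] = None

    def fit(
        self,
        pos_train: Sequence[str] = (),
        neg_train: Sequence[str] = (),
        corpus: Sequence[str] = (),
        seed: int = 0,
        **overrides,
    ):
        """Fit encoder state on training data; returns the profile/model.

        BPB/NPPS use the labelled positive/negative sets; W2V trains on
        ``corpus`` (all training sequences, labels ignored).
        """
        if not self.requires_fit:
            return None
        params = {**self.default_params, **overrides}
        if self.id == "W2V":
            return self._fit(list(corpus), seed=seed, **params)
        return self._fit(list(pos_train), list(neg_train), **params)

    def transform(self, seq: str, state=None, **overrides) -> FeatureVector:
        if self.requires_fit:
            if state is None:
                raise EncoderError(f"{self.id} requires a fitted profile")
            return self._transform(seq, state)
        params = {**self.default_params, **overrides}
        return self._transform(seq, **params)

    def n_features(self, L: int, state=None) -> int:
        probe = "ACGU" * (L // 4 + 1)
        return len(self.transform(probe[:L], state) if self.requires_fit
                   else self.transform(probe[:L]))


def encoder_registry() -> list[EncoderSpec]:
    """All 18 encoders with their default parameters.

    Exactly three (BPB, NPPS, W2V) are fit-dependent.
    """
    return [
        EncoderSpec("Binary", False, {}, binary_encode),
        EncoderSpec("ENAC", False, {"window": 5}, enac_encode),
        EncoderSpec("NCP", False, {}, ncp_encode),
        EncoderSpec("ANF", False, {}, anf_encode),
        EncoderSpec("EIIP", False, {}, eiip_encode),
        EncoderSpec("DNC", False, {}, dnc_encode),
        EncoderSpec("TNC", False, {}, tnc_encode),
        EncoderSpec("CKSNAP", False, {"gaps": (0, 1, 2, 3, 4, 5)}, cksnap_encode),
        EncoderSpec("RCKmer", False, {"k": 2}, rckmer_encode),
        EncoderSpec("PseEIIP", False, {}, pse_eiip_encode),
        EncoderSpec("BPB", True, {"pseudocount": 0.25}, bpb_encode, bpb_fit),
        EncoderSpec("CTD", False, {}, ctd_encode),
        EncoderSpec("Kmer", False, {"k": 4}, kmer_encode),
        EncoderSpec("NCP-ND", False, {}, ncp_nd_encode),
        EncoderSpec("NPS", False, {"d_max": 3}, nps_encode),
        EncoderSpec("NPPS", True, {"k": 0, "pseudocount": 0.25}, npps_encode, npps_fit),
        EncoderSpec(
            "PseKNC",
            False,
            {"spec": None},
            lambda seq, spec=None: pseknc_encode(seq, spec),
        ),
        EncoderSpec("W2V", True, {"dim": 64, "window": 5}, w2v_encode, w2v_fit),
    ]


def get_encoder(encoder_id: str) -> EncoderSpec:
    for spec in encoder_registry():
        if spec.id == encoder_id:
            return spec
    raise KeyError(f"unknown encoder {encoder_id!r}")
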