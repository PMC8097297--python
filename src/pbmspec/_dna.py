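"""Low-level nucleotide utilities shared across the package.

Sequences are handled both as Python strings over {A,C,G,T} and as 2-bit
integer codes (A=0, C=1, G=2, T=3).  A k-mer maps to the integer
``sum(code(base_j) * 4**(k-1-j))``; the *canonical* form of a k-mer is the
lexicographically (equivalently numerically) smaller of the k-mer and its
reverse complement.  For k=8 there are exactly 32,896 canonical classes:
(4**8 - 256)/2 + 256, the 256 being reverse-complement palindromes.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array of 2-bit base codes."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = seq[int(np.argmax(out == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def encode_matrix(seqs) -> np.ndarray:
    """Encode equal-length DNA strings into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    joined = "".join(seqs).upper()
    flat = encode(joined)
    return flat.reshape(len(seqs), lengths.pop())


def decode(codes) -> str:
    return "".join(BASES[c] for c in codes)


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append(BASES[(code >> (2 * j)) & 3])
    return "".join(out)


@lru_cache(maxsize=None)
def revcomp_code_table(k: int) -> np.ndarray:
    """rc[c] = code of the reverse complement of the k-mer with code c."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (c & 3))
        c >>= 2
    return rc


@lru_cache(maxsize=None)
def canonical_codes(k: int = 8):
    """Return (sorted canonical codes, code -> class-index lookup table).

    The lookup table maps *any* k-mer code (canonical or not) to the compact
    index of its canonical class.
    """
    rc = revcomp_code_table(k)
    codes = np.arange(4**k, dtype=np.int64)
    canon = np.minimum(codes, rc)
    canon_sorted = np.unique(canon)
    index_of_canon = np.full(4**k, -1, dtype=np.int64)
    index_of_canon[canon_sorted] = np.arange(canon_sorted.size)
    class_index = index_of_canon[canon]
    return canon_sorted, class_index


def n_canonical_classes(k: int = 8) -> int:
    return int(canonical_codes(k)[0].size)


@lru_cache(maxsize=None)
def canonical_kmer_strings(k: int = 8) -> tuple:
    """Canonical k-mer strings in compact-index (numeric) order."""
    canon, _ = canonical_codes(k)
    return tuple(decode_kmer(int(c), k) for c in canon)


def canonicalize(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_palindrome(kmer: str) -> bool:
    return kmer == revcomp(kmer.upper())


def window_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """(n, L) base-code matrix -> (n, L-k+1) int64 matrix of k-mer codes."""
    n, L = mat.shape
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length {L}")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(mat.astype(np.int64), k, axis=1)
    return windows @ powers


def class_memberships(seqs, k: int = 8):
    """Per-probe unique canonical-class membership.

    Returns (probe_idx, class_idx) int64 arrays: one entry per (probe, class)
    pair in which the class's k-mer or its reverse complement occurs in the
    probe at least once.  Multiple occurrences in one probe count once.
    """
    _, class_index = canonical_codes(k)
    mat = encode_matrix(seqs)
    codes = window_codes(mat, k)
    cls = class_index[codes]
    cls.sort(axis=1)  # dedupe within probe
    keep = np.ones_like(cls, dtype=bool)
    keep[:, 1:] = cls[:, 1:] != cls[:, :-1]
    n, w = cls.shape
    probe_idx = np.repeat(np.arange(n, dtype=np.int64), w)[keep.ravel()]
    class_idx = cls.ravel()[keep.ravel()]
    return probe_idx, class_idx


def random_debruijn_sequence(k: int, rng: np.random.Generator) -> str:
    """A random linear DNA sequence containing every k-mer exactly once.

    Constructed as a uniform-ish random Eulerian circuit of the order-k
    de Bruijn graph (nodes = (k-1)-mers, edges = k-mers) via Hierholzer's
    algorithm with per-node shuffled edge order, then linearized; length is
    4**k + k - 1.
    """
    n_nodes = 4 ** (k - 1)
    order = rng.permuted(np.tile(np.arange(4, dtype=np.int8), (n_nodes, 1)), axis=1)
    ptr = np.zeros(n_nodes, dtype=np.int64)
    start = int(rng.integers(n_nodes))
    stack = [start]
    circuit = []
    while stack:
        v = stack[-1]
        if ptr[v] < 4:
            b = int(order[v, ptr[v]])
            ptr[v] += 1
            stack.append((v * 4 + b) % n_nodes)
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    # circuit is the node walk; sequence = first node's (k-1)-mer, then the
    # trailing base of each subsequent node.
    head = decode_kmer(circuit[0], k - 1)
    tail = "".join(BASES[v & 3] for v in circuit[1:])
    return head + tail
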