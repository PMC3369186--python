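"""Sequence I/O and k-mer arithmetic.

FASTA/FASTQ reading (plain or gzip), contig writing, 2-bit k-mer encoding
(A=00, C=01, G=10, T=11, leftmost base in the most significant bits),
reverse complement and canonical form.  Everything downstream works on the
integer codes produced here; the sequence strings themselves are only kept
on :class:`Read` records.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "Read",
    "KmerCode",
    "ParseError",
    "read_sequences",
    "write_fastq",
    "write_contigs",
    "reverse_complement",
    "encode_kmer",
    "decode_kmer",
    "canonical",
    "canonical_codes",
    "FORWARD",
    "REVERSE",
]

#: strand flags used throughout the package
FORWARD = 0
REVERSE = 1

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code lookup; 255 marks non-ACGT
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_LUT[_b] = _v
    _BASE_LUT[_b + 32] = _v  # lowercase

_BASES = "ACGT"


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


@dataclass
class Read:
    """A single sequencing read.

    ``qual`` is optional; when present it must have the same length as
    ``seq``.  The assembler ignores qualities entirely.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class KmerCode:
    """A 2-bit packed k-mer: ``bits < 4**k``, leftmost base in the high bits."""

    bits: int
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.bits < 4 ** self.k:
            raise ValueError(f"bits {self.bits} out of range for k={self.k}")

    def decode(self) -> str:
        return decode_kmer(self.bits, self.k)


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _detect_format(handle) -> Optional[str]:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if not first:
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"cannot detect format from leading character {first!r}")


def read_sequences(
    path: Union[str, Path], format: str = "auto"
) -> Iterator[Read]:
    """Yield :class:`Read` records from a FASTA or FASTQ file, in file order.

    Multi-line FASTA records are concatenated and sequences are uppercased.
    ``format='auto'`` sniffs the first character ('>' vs '@').  Gzip input
    is handled transparently for paths ending in ``.gz``.
    """
    if format not in ("fasta", "fastq", "auto"):
        raise ValueError(f"unknown format {format!r}")
    with _open_text(path) as handle:
        fmt = format
        if fmt == "auto":
            fmt = _detect_format(handle)
            if fmt is None:  # empty file -> empty stream
                return
        try:
            for rec in SeqIO.parse(handle, fmt):
                qual = None
                if fmt == "fastq":
                    quals = rec.letter_annotations.get("phred_quality")
                    if quals is not None:
                        qual = "".join(chr(q + 33) for q in quals)
                yield Read(rec.id, str(rec.seq).upper(), qual)
        except ValueError as exc:  # Biopython reports the offending record
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Sequence[Read], path: Union[str, Path]) -> None:
    """Write reads as FASTQ; missing qualities are filled with 'I'."""
    with open(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_contigs(contigs, path: Union[str, Path]) -> None:
    """Write contigs as 80-column wrapped FASTA.

    Headers follow ``contig_<index>_len_<length>_cov_<mean coverage>`` with
    coverage printed to one decimal.
    """
    with open(path, "wt") as fh:
        for i, contig in enumerate(contigs):
            seq = contig.seq if hasattr(contig, "seq") else str(contig)
            cov = getattr(contig, "mean_cov", 0.0)
            fh.write(f">contig_{i}_len_{len(seq)}_cov_{cov:.1f}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed.  Non-ACGT characters are an error."""
    out = seq.translate(_COMPLEMENT)[::-1]
    bad = set(out) - set("ACGTacgt")
    if bad:
        raise ValueError(f"non-ACGT character(s) in sequence: {sorted(bad)}")
    return out


def encode_kmer(kmer: str) -> KmerCode:
    """Pack an ACGT string into 2 bits per base (A=00,C=01,G=10,T=11)."""
    bits = 0
    for ch in kmer:
        v = _BASE_LUT[ord(ch)]
        if v == 255:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        bits = (bits << 2) | int(v)
    return KmerCode(bits, len(kmer))


def decode_kmer(bits: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(bits >> shift) & 3])
    return "".join(out)


def rc_code(bits: int, k: int) -> int:
    """Reverse complement of a packed k-mer, as an integer."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (bits & 3))
        bits >>= 2
    return out


def canonical(kmer: str) -> tuple[KmerCode, int]:
    """Return the lexicographically smaller of *kmer* / its reverse
    complement (as a :class:`KmerCode`) plus the strand of the input
    (:data:`FORWARD` if the input itself is canonical).

    With the A<C<G<T bit mapping, lexicographic string order coincides with
    numeric order of the packed codes.
    """
    fwd = encode_kmer(kmer)
    rev = rc_code(fwd.bits, fwd.k)
    if fwd.bits <= rev:
        return fwd, FORWARD
    return KmerCode(rev, fwd.k), REVERSE


def check_odd_k(k: int, allow_even: bool = False) -> None:
    """k must be odd so no k-mer equals its own reverse complement."""
    if k % 2 == 0:
        if not allow_even:
            raise ValueError(f"k={k} is even; use odd k (or allow_even=True)")
        warnings.warn(
            f"k={k} is even: palindromic k-mers are their own reverse "
            "complement and strand flags become ambiguous",
            stacklevel=2,
        )


def canonical_codes(seq: str, k: int):
    """Vectorised canonical codes for every k-mer of *seq*.

    Returns ``(codes, strands, valid)`` as numpy arrays of length
    ``len(seq) - k + 1`` (empty when the sequence is shorter than k):

    * ``codes``   uint64 canonical 2-bit codes (undefined where invalid)
    * ``strands`` uint8, FORWARD / REVERSE of the k-mer as read
    * ``valid``   bool, False for windows containing non-ACGT characters

    Requires ``k <= 31`` so codes fit in 62 bits; larger k falls back to a
    scalar path.
    """
    n = len(seq) - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.uint64)
        return z, np.empty(0, dtype=np.uint8), np.empty(0, dtype=bool)
    if k > 31:
        return _canonical_codes_scalar(seq, k)

    b = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    invalid = b == 255
    b2 = np.where(invalid, 0, b).astype(np.uint64)
    comp = np.uint64(3) - b2

    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    for j in range(k):
        fwd = fwd * four + b2[j : j + n]
        rev = rev * four + comp[k - 1 - j : k - 1 - j + n]

    cs = np.concatenate([[0], np.cumsum(invalid)])
    valid = (cs[k:] - cs[:n]) == 0
    strands = (rev < fwd).astype(np.uint8)
    codes = np.minimum(fwd, rev)
    return codes, strands, valid


def _canonical_codes_scalar(seq: str, k: int):
    n = len(seq) - k + 1
    codes = np.zeros(n, dtype=object)
    strands = np.zeros(n, dtype=np.uint8)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        window = seq[i : i + k]
        try:
            code, strand = canonical(window)
        except ValueError:
            continue
        codes[i] = code.bits
        strands[i] = strand
        valid[i] = True
    return codes, strands, valid
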