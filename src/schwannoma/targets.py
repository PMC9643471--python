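"""Mutational target sizes of tumour-suppressor genes.

A site on a coding sequence is *sensitive* if a single-base substitution or a
small deletion there creates a premature stop codon (TAA/TAG/TGA), truncating
the protein.  The overall target size of a gene decomposes as

    n_gene = l_gene + m_gene

where ``l_gene`` counts substitution-sensitive sites (each raw hit weighted by
1/3, the Jukes-Cantor equal-rate assumption: only one of the three possible
substitutions at a base produces the required change) and ``m_gene`` is the
expected number of deletion-sensitive sites under a geometric indel-length
distribution f(k) = A q^|k|, symmetric in insertions and deletions.  Because
insertions never create the junction stop codons counted here, they contribute
zero to the numerator of the length average but full weight to its
denominator.

Counting is restricted to the longest open reading frame; ambiguity codes are
rejected so that the counts are reproducible integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ALPHABET = frozenset("ACGT")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

__all__ = [
    "CodingSequence",
    "IndelLengthDistribution",
    "GeneTargetProfile",
    "NoOrfError",
    "AmbiguousBaseError",
    "extract_longest_orf",
    "count_substitution_sensitive",
    "count_deletion_sensitive",
    "deletion_profile",
    "expected_indel_sensitive",
    "bozic_indel_approximation",
    "profile_gene",
    "read_sequences",
    "profiles_to_frames",
]


class NoOrfError(ValueError):
    """No ATG-initiated open reading frame found in any forward frame."""


class AmbiguousBaseError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""

    def __init__(self, base: str, position: int):
        self.base = base
        self.position = position
        super().__init__(
            f"ambiguous or invalid base {base!r} at position {position}; "
            "ambiguity codes are rejected so that site counts are "
            "reproducible integers"
        )


def _validate_bases(bases: str) -> str:
    bases = bases.upper().replace("U", "T")
    for i, ch in enumerate(bases):
        if ch not in ALPHABET:
            raise AmbiguousBaseError(ch, i)
    return bases


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence over {A, C, G, T}.

    ``frame_origin`` is the 0-based index of the first base of the first codon
    in the *source* sequence (informational once the ORF is extracted).
    ``has_terminal_stop`` flags whether the final codon is a stop codon; the
    terminal stop is retained but never counted as sensitive.
    """

    identifier: str
    bases: str
    frame_origin: int = 0
    source_format: str = "RAW"
    has_terminal_stop: bool = False

    def __post_init__(self):
        object.__setattr__(self, "bases", _validate_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def codons(self) -> list[str]:
        b = self.bases
        return [b[i : i + 3] for i in range(0, len(b) - len(b) % 3, 3)]

    @property
    def coding_length(self) -> int:
        """Length in bases excluding the terminal stop codon, if present."""
        n = len(self.bases) - len(self.bases) % 3
        return n - 3 if self.has_terminal_stop else n


def extract_longest_orf(seq: "CodingSequence | str", identifier: str = "orf") -> CodingSequence:
    """Return the longest ATG-to-stop open reading frame.

    All three forward frames are scanned; the longest ORF wins, ties broken by
    the lowest start coordinate.  An ORF runs from an ATG to the first in-frame
    stop codon (retained, flagged non-countable) or to the sequence end.
    """
    if isinstance(seq, CodingSequence):
        bases, identifier = seq.bases, seq.identifier
    else:
        bases = _validate_bases(seq)
    if not bases:
        raise NoOrfError("empty sequence")

    best: tuple[int, int, bool] | None = None  # (start, length, has_stop)
    for frame in range(3):
        i = frame
        while i + 3 <= len(bases):
            if bases[i : i + 3] == START_CODON:
                j = i
                has_stop = False
                while j + 3 <= len(bases):
                    if bases[j : j + 3] in STOP_CODONS:
                        has_stop = True
                        j += 3
                        break
                    j += 3
                length = j - i
                if best is None or length > best[1] or (length == best[1] and i < best[0]):
                    best = (i, length, has_stop)
                # restart scan after this ATG so nested ATGs are considered
            i += 3
    if best is None:
        raise NoOrfError(f"no ATG-initiated open reading frame in {identifier!r}")
    start, length, has_stop = best
    return CodingSequence(
        identifier=identifier,
        bases=bases[start : start + length],
        frame_origin=start,
        source_format="RAW",
        has_terminal_stop=has_stop,
    )


def count_substitution_sensitive(orf: CodingSequence) -> tuple[int, float]:
    """Count sites where a single-base substitution creates a stop codon.

    Each distinct substitution reaching TAA/TAG/TGA counts once (a base two
    stops away counts twice); the total is then weighted by 1/3 for the
    equal-rate substitution model.  The initiator ATG and the terminal stop
    codon are excluded.

    Returns ``(raw_multiplicity, l_gene)`` with ``l_gene = raw/3``.
    """
    codons = orf.codons
    n_coding = len(codons) - (1 if orf.has_terminal_stop else 0)
    if n_coding < 2:
        raise ValueError("ORF shorter than 2 codons has no countable sites")
    raw = 0
    for idx in range(1, n_coding):  # skip initiator codon
        codon = codons[idx]
        if codon in STOP_CODONS:
            continue
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                if codon[:pos] + alt + codon[pos + 1 :] in STOP_CODONS:
                    raw += 1
    return raw, raw / 3.0


def _junction_codon_indices(i: int, k: int) -> tuple[int, ...]:
    """Codon indices (original reading frame) overlapping a deletion junction."""
    j = i // 3
    return (j,) if k % 3 == 0 else (j, j + 1)


def count_deletion_sensitive(orf: CodingSequence, k: int) -> int:
    """Count start positions where deleting ``k`` bases creates a stop codon.

    Deletion of length ``k`` at position ``i`` removes bases ``[i, i+k)``
    (0-based, half-open); the re-joined sequence is read in the original
    frame, and the site counts as sensitive iff a codon overlapping the
    junction (the codon containing position ``i``, plus the following codon
    when ``k`` is not a multiple of 3) is a stop codon where the original
    codon at that index was not.  Deletions spanning the terminal stop codon
    are not counted, and a junction codon consisting entirely of the original
    terminal stop (an in-frame deletion that merely shifts the normal stop
    forward) is a truncation, not a nonsense gain, and does not count.
    """
    bases = orf.bases
    limit = orf.coding_length
    if not 1 <= k <= len(bases) - 3:
        raise ValueError(f"deletion length k={k} out of range [1, {len(bases) - 3}]")
    count = 0
    for i in range(0, limit - k + 1):
        mutant = bases[:i] + bases[i + k :]
        for j in _junction_codon_indices(i, k):
            new_codon = mutant[3 * j : 3 * j + 3]
            if len(new_codon) < 3:
                continue
            # source positions of this codon in the original sequence
            sources = [q if q < i else q + k for q in range(3 * j, 3 * j + 3)]
            if all(q >= limit for q in sources):
                continue  # the original terminal stop, shifted
            old_codon = bases[3 * j : 3 * j + 3]
            if new_codon in STOP_CODONS and old_codon not in STOP_CODONS:
                count += 1
                break
    return count


@dataclass(frozen=True)
class IndelLengthDistribution:
    """Geometric indel-length weights f(k) = A q^|k| over nonzero lengths.

    ``q`` is the per-base decay ratio of indel frequency with length
    (default 0.53, from empirical indel-length spectra); ``k_max`` truncates
    the sum where the geometric tail is negligible.  With ``symmetric=True``
    insertions (k < 0) mirror deletions (k > 0) in weight.
    """

    q: float = 0.53
    k_max: int = 40
    symmetric: bool = True
    tail_tolerance: float = 1e-9

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("decay ratio q must lie in (0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be a positive integer")
        # tail mass beyond k_max, relative to the total geometric mass
        tail = self.q ** self.k_max
        if tail > self.tail_tolerance:
            raise ValueError(
                f"geometric tail mass q^k_max = {tail:.3g} exceeds tolerance "
                f"{self.tail_tolerance:g}; increase k_max"
            )

    def deletion_weight(self, k: int) -> float:
        return self.q ** k

    @property
    def total_weight(self) -> float:
        one_side = sum(self.q ** k for k in range(1, self.k_max + 1))
        return 2.0 * one_side if self.symmetric else one_side


def deletion_profile(orf: CodingSequence, dist: IndelLengthDistribution) -> dict[int, int]:
    """m(k) for k = 1 .. min(k_max, len-3)."""
    upper = min(dist.k_max, len(orf.bases) - 3)
    return {k: count_deletion_sensitive(orf, k) for k in range(1, upper + 1)}


def expected_indel_sensitive(
    orf: CodingSequence,
    dist: IndelLengthDistribution | None = None,
    m_profile: Mapping[int, int] | None = None,
) -> float:
    """Weighted average m_gene = sum_k m(k) f(k) / sum_k f(k).

    Insertions contribute zero to the numerator but (when the distribution is
    symmetric) full weight to the denominator, halving the deletion-only
    average.  The normalisation constant of f cancels.
    """
    dist = dist or IndelLengthDistribution()
    if m_profile is None:
        m_profile = deletion_profile(orf, dist)
    numerator = sum(m * dist.deletion_weight(k) for k, m in m_profile.items())
    return numerator / dist.total_weight


def bozic_indel_approximation(l_gene: float) -> float:
    """Empirical shortcut m_gene ~= 0.74 l_gene (pan-cancer indel/SNV ratio)."""
    if l_gene < 0:
        raise ValueError("l_gene must be nonnegative")
    return 0.74 * l_gene


@dataclass(frozen=True)
class GeneTargetProfile:
    """Per-gene mutational target sizes: n = l + m."""

    identifier: str
    raw_substitution_multiplicity: int
    l_gene: float
    m_profile: Mapping[int, int] = field(default_factory=dict)
    m_gene: float = 0.0

    @property
    def n_gene(self) -> float:
        return self.l_gene + self.m_gene


def profile_gene(
    seq: "CodingSequence | str",
    dist: IndelLengthDistribution | None = None,
    cds_mode: str = "longest-orf",
    identifier: str = "gene",
) -> GeneTargetProfile:
    """Full target-size profile of a coding sequence.

    ``cds_mode='longest-orf'`` scans for the longest ATG-initiated ORF;
    ``'annotated'`` treats the input as an already-curated CDS (in frame,
    possibly ending in a stop codon) and skips the ORF search.
    """
    dist = dist or IndelLengthDistribution()
    if cds_mode == "longest-orf":
        orf = extract_longest_orf(seq, identifier=identifier)
    elif cds_mode == "annotated":
        if isinstance(seq, CodingSequence):
            orf = seq
        else:
            bases = _validate_bases(seq)
            has_stop = len(bases) >= 3 and bases[-3:] in STOP_CODONS and len(bases) % 3 == 0
            orf = CodingSequence(identifier, bases, has_terminal_stop=has_stop)
    else:
        raise ValueError(f"unknown cds_mode {cds_mode!r}")
    raw, l_gene = count_substitution_sensitive(orf)
    m_profile = deletion_profile(orf, dist)
    m_gene = expected_indel_sensitive(orf, dist, m_profile)
    return GeneTargetProfile(
        identifier=orf.identifier,
        raw_substitution_multiplicity=raw,
        l_gene=l_gene,
        m_profile=m_profile,
        m_gene=m_gene,
    )


def read_sequences(path: "str | Path", fmt: str = "fasta") -> list[CodingSequence]:
    """Read coding sequences from FASTA or GenBank/EMBL flat files.

    For GenBank/EMBL records, CDS features are extracted (join() locations
    honoured via Biopython's location arithmetic, converting the format's
    1-based inclusive coordinates internally); each CDS becomes one
    CodingSequence in 'annotated' frame.
    """
    from Bio import SeqIO

    fmt = fmt.lower()
    out: list[CodingSequence] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(CodingSequence(rec.id, str(rec.seq), source_format="FASTA"))
    elif fmt in ("genbank", "gb", "embl"):
        biofmt = "embl" if fmt == "embl" else "genbank"
        for rec in SeqIO.parse(str(path), biofmt):
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", [rec.id]))[0]
                cds = str(feat.extract(rec.seq))
                has_stop = len(cds) % 3 == 0 and cds[-3:].upper() in STOP_CODONS
                out.append(
                    CodingSequence(
                        name,
                        cds,
                        frame_origin=int(feat.location.start),
                        source_format="GENBANK_EMBL",
                        has_terminal_stop=has_stop,
                    )
                )
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def profiles_to_frames(profiles: Iterable[GeneTargetProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary table (one row per gene) and long-format m(k) table."""
    profiles = list(profiles)
    summary = pd.DataFrame(
        {
            "id": [p.identifier for p in profiles],
            "raw_multiplicity": [p.raw_substitution_multiplicity for p in profiles],
            "l": [p.l_gene for p in profiles],
            "m": [p.m_gene for p in profiles],
            "n": [p.n_gene for p in profiles],
        }
    )
    rows = [
        {"id": p.identifier, "k": k, "m_k": m}
        for p in profiles
        for k, m in sorted(p.m_profile.items())
    ]
    return summary, pd.DataFrame(rows, columns=["id", "k", "m_k"])
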