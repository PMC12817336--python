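"""Nonsense-variant sequence reasoning for readthrough assay design.

Given a coding sequence and an HGVS-like ``c.`` substitution, this module
locates the premature termination codon (PTC), extracts the 23-nt stop codon
context (SCC; stop plus ten nucleotides on each side), ranks the stop codon's
leakiness (UGA > UAG > UAA), scores distance to the high-readthrough motif
UGA CUAG, lists the amino acids near-cognate tRNAs insert at each stop, and
estimates the truncated product's length and mass.

All sequence storage uses the DNA alphabet; RNA input (U) is normalized to T
on entry.  ``c.`` coordinates are 1-based within the CDS, starting at the A
of the initiator ATG.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Literal

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

STOP_CODONS = ("TAA", "TAG", "TGA")
GAP = "-"

#: Leakiness ordering of the three stop codons: UGA is the most
#: readthrough-prone, UAA terminates most efficiently.
LEAKINESS_RANK = {"TGA": 1, "TAG": 2, "TAA": 3}
LEAKINESS_LABEL = {"TGA": "leaky", "TAG": "intermediate", "TAA": "tight"}

#: High-readthrough downstream motif (stop + 4 nt), DNA alphabet.
HIGH_READTHROUGH_MOTIF = "TGACTAG"

#: Amino acids favored for near-cognate incorporation at each stop codon.
NEAR_COGNATE_AA = {
    "TGA": frozenset({"Trp", "Cys", "Arg"}),
    "TAG": frozenset({"Gln", "Tyr", "Lys"}),
    "TAA": frozenset({"Gln", "Tyr", "Lys"}),
}

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

#: Printed dual-reporter SCC oligos (forward strands) with cloning adapters
#: still attached; used to verify adapter trimming recovers a stop-containing
#: insert.
REPORTER_OLIGOS = {
    "p.Q82X": "GTCACCGGTGGCACTGGTAGGGCGAGGGGCT",
    "p.W188X": "GTCACCGACTCTTAGAGTGATTCCATCCACT",
    "p.Q427X": "GTCACCGGCTGGGAATTTAAGGAGATCTGAT",
}

#: Default cloning-adapter definition for the reporter oligo family
#: (BsrGI-compatible leader, single-base 3' overhang).  Configurable because
#: the vector junction is a design choice, not a sequence property.
DEFAULT_OLIGO_ADAPTERS = {"leading": "GTCACC", "trailing_len": 1}


def normalize_dna(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding DNA sequence (ATG ... stop).

    ``signal_peptide_len`` is the number of N-terminal residues cleaved from
    the precursor (27 for the lysosomal alpha-L-fucosidase studied here).
    Validation enforces frame, alphabet, initiator and terminal stop;
    internal in-frame stops are permitted because PTC-bearing variants are
    exactly what this module manipulates (``require_no_internal_stop`` is
    available for wild-type sequences).
    """

    id: str
    cds: str
    signal_peptide_len: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", normalize_dna(self.cds))
        cds = self.cds
        if len(cds) < 6 or len(cds) % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {len(cds)} is not a positive multiple of 3")
        if set(cds) - set("ACGT"):
            raise ValueError(f"{self.id}: CDS contains non-ACGT characters")
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS does not start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end with a stop codon")
        if self.signal_peptide_len is not None and self.signal_peptide_len < 0:
            raise ValueError(f"{self.id}: negative signal_peptide_len")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codon(self, index: int) -> str:
        """1-based codon accessor; codon k spans CDS positions 3k-2..3k."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range 1..{self.n_codons}")
        return self.cds[3 * (index - 1) : 3 * index]

    def check_no_internal_stop(self) -> None:
        for k in range(1, self.n_codons):
            if self.codon(k) in STOP_CODONS:
                raise ValueError(f"{self.id}: internal stop codon {self.codon(k)} at codon {k}")

    def translate(self, to_first_stop: bool = True) -> str:
        prot = str(Seq(self.cds).translate())
        if to_first_stop and "*" in prot:
            return prot[: prot.index("*")]
        return prot.rstrip("*")


@dataclass(frozen=True)
class CdsSubstitution:
    """Single-nucleotide substitution in 1-based CDS coordinates."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", normalize_dna(self.ref_base))
        object.__setattr__(self, "alt_base", normalize_dna(self.alt_base))
        if self.position < 1:
            raise ValueError(f"substitution position {self.position} must be >= 1")
        for base, name in ((self.ref_base, "ref_base"), (self.alt_base, "alt_base")):
            if base not in "ACGT" or len(base) != 1:
                raise ValueError(f"{name} {base!r} is not a single DNA base")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")

    @property
    def hgvs_c(self) -> str:
        return f"c.{self.position}{self.ref_base}>{self.alt_base}"


_HGVS_RE = re.compile(r"^c\.(\d+)([ACGTU])>([ACGTU])$", re.IGNORECASE)


def parse_hgvs_c(text: str) -> CdsSubstitution:
    """Parse an HGVS-like coding substitution such as ``c.244C>T``."""
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse coding substitution {text!r} (expected e.g. c.244C>T)")
    return CdsSubstitution(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class StopContext:
    """A premature stop codon and its 23-nt sequence context."""

    codon_index: int
    stop_codon: str  # DNA alphabet (TAA/TAG/TGA)
    upstream_10nt: str  # padded with '-' near the CDS start
    downstream_10nt: str  # padded with '-' near the CDS end
    leakiness_rank: int
    leakiness_label: str
    padded: bool

    @property
    def scc_23nt(self) -> str:
        return self.upstream_10nt + self.stop_codon + self.downstream_10nt

    @property
    def stop_codon_rna(self) -> str:
        return self.stop_codon.replace("T", "U")


def codon_index(position: int) -> int:
    """Map a 1-based cDNA coordinate to its 1-based codon number."""
    if position < 1:
        raise ValueError(f"cDNA position {position} must be >= 1")
    return math.ceil(position / 3)


def apply_substitution(seq: CodingSequence, sub: CdsSubstitution) -> CodingSequence:
    """Return a copy of ``seq`` with the substitution applied.

    The reference base is checked against the sequence and a mismatch is an
    explicit error reporting expected vs found.
    """
    if sub.position > len(seq.cds):
        raise ValueError(
            f"position {sub.position} beyond CDS length {len(seq.cds)} of {seq.id}"
        )
    found = seq.cds[sub.position - 1]
    if found != sub.ref_base:
        raise ValueError(
            f"reference mismatch at c.{sub.position} of {seq.id}: "
            f"substitution expects {sub.ref_base}, sequence has {found}"
        )
    cds = seq.cds[: sub.position - 1] + sub.alt_base + seq.cds[sub.position :]
    return replace(seq, id=f"{seq.id}:{sub.hgvs_c}", cds=cds)


def leakiness_rank(stop_codon: str) -> tuple[int, str]:
    """Ordinal leakiness of a stop codon (1 = most readthrough-prone)."""
    codon = normalize_dna(stop_codon)
    if codon not in STOP_CODONS:
        raise ValueError(f"{stop_codon!r} is not a stop codon")
    return LEAKINESS_RANK[codon], LEAKINESS_LABEL[codon]


def extract_scc(seq: CodingSequence, index: int) -> StopContext:
    """Extract the stop codon at ``index`` plus 10 nt on each side.

    The SCC is 23 nt when both flanks are available; otherwise the missing
    positions are padded with ``-`` and ``padded`` is set.
    """
    stop = seq.codon(index)
    if stop not in STOP_CODONS:
        raise ValueError(f"codon {index} of {seq.id} is {stop}, not a stop codon")
    start = 3 * (index - 1)
    up = seq.cds[max(0, start - 10) : start]
    down = seq.cds[start + 3 : start + 13]
    padded = len(up) < 10 or len(down) < 10
    up = up.rjust(10, GAP)
    down = down.ljust(10, GAP)
    rank, label = leakiness_rank(stop)
    return StopContext(
        codon_index=index,
        stop_codon=stop,
        upstream_10nt=up,
        downstream_10nt=down,
        leakiness_rank=rank,
        leakiness_label=label,
        padded=padded,
    )


def classify_variant(
    seq_before: CodingSequence, seq_after: CodingSequence
) -> tuple[Literal["nonsense", "missense", "silent"], StopContext | None]:
    """Classify a single-base change and return the PTC context if nonsense.

    The two sequences must be equal length and differ at exactly one
    position.  A change is nonsense iff the altered codon becomes a stop
    codon upstream of the natural (terminal) stop.
    """
    a, b = seq_before.cds, seq_after.cds
    if len(a) != len(b):
        raise ValueError("sequences have unequal length")
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if len(diffs) != 1:
        raise ValueError(f"sequences differ at {len(diffs)} positions, expected exactly 1")
    idx = codon_index(diffs[0] + 1)
    before_codon = seq_before.codon(idx)
    after_codon = seq_after.codon(idx)
    if after_codon in STOP_CODONS and idx < seq_after.n_codons:
        return "nonsense", extract_scc(seq_after, idx)
    aa_before = str(Seq(before_codon).translate())
    aa_after = str(Seq(after_codon).translate())
    return ("silent" if aa_before == aa_after else "missense"), None


def motif_distance(context: StopContext) -> int:
    """Hamming distance of (stop + 4 downstream nt) to the UGA CUAG motif."""
    window = context.stop_codon + context.downstream_10nt[:4]
    if GAP in window:
        raise ValueError("insufficient downstream context for motif comparison (need 4 nt)")
    window = normalize_dna(window)
    return sum(1 for a, b in zip(window, HIGH_READTHROUGH_MOTIF) if a != b)


def near_cognate_candidates(stop_codon: str) -> frozenset[str]:
    """Amino acids favored for near-cognate incorporation at a stop codon."""
    codon = normalize_dna(stop_codon)
    if codon not in STOP_CODONS:
        raise ValueError(f"{stop_codon!r} is not a stop codon")
    return NEAR_COGNATE_AA[codon]


def codons_for_aa3(aa3: str) -> list[str]:
    """All standard-code DNA codons encoding a three-letter amino acid."""
    want = {one for one, three in _AA3.items() if three == aa3}
    if not want:
        raise ValueError(f"unknown amino acid {aa3!r}")
    bases = "ACGT"
    return [
        c
        for c in (x + y + z for x in bases for y in bases for z in bases)
        if str(Seq(c).translate()) in want
    ]


def predicted_truncation(
    seq: CodingSequence,
    index: int,
    convention: Literal["precursor", "mature"] = "precursor",
    mass_mode: Literal["sequence_average", "sequence_monoisotopic", "mean_residue"] = "sequence_average",
    mean_residue_da: float = 110.0,
) -> tuple[int, float]:
    """Residue count and approximate mass (kDa) of the truncated product.

    ``precursor`` counts all residues before the PTC; ``mature`` subtracts
    the cleaved signal peptide.  Mass is either summed from the actual
    residues (Biopython average or monoisotopic tables) or estimated as
    ``count * mean_residue_da``.  Glycosylation (which adds ~2-3 kDa to the
    mature enzyme studied here) is not modeled.
    """
    if index <= 1:
        raise ValueError("codon index must be > 1 for a nonempty truncation product")
    if index >= seq.n_codons and seq.codon(seq.n_codons) in STOP_CODONS and index > seq.n_codons:
        raise ValueError("codon index beyond CDS")
    n_res = index - 1
    residues = str(Seq(seq.cds[: 3 * n_res]).translate())
    if "*" in residues:
        residues = residues[: residues.index("*")]
        n_res = len(residues)
    if convention == "mature":
        if seq.signal_peptide_len is None:
            raise ValueError("mature convention requires signal_peptide_len")
        n_res = max(0, n_res - seq.signal_peptide_len)
        residues = residues[seq.signal_peptide_len :]
    elif convention != "precursor":
        raise ValueError(f"unknown convention {convention!r}")

    if mass_mode == "mean_residue":
        mass_da = n_res * mean_residue_da
    elif mass_mode in ("sequence_average", "sequence_monoisotopic"):
        if n_res == 0:
            mass_da = 0.0
        else:
            mass_da = molecular_weight(
                residues, seq_type="protein", monoisotopic=mass_mode.endswith("monoisotopic")
            )
    else:
        raise ValueError(f"unknown mass_mode {mass_mode!r}")
    return n_res, mass_da / 1000.0


def trim_reporter_oligo(oligo: str, adapters: dict | None = None) -> str:
    """Strip declared cloning adapters from a reporter SCC oligo.

    ``adapters`` declares a ``leading`` sequence and a ``trailing_len`` base
    count; the remainder is the SCC insert.
    """
    cfg = dict(DEFAULT_OLIGO_ADAPTERS, **(adapters or {}))
    seq = normalize_dna(oligo)
    lead = normalize_dna(cfg["leading"])
    if not seq.startswith(lead):
        raise ValueError(f"oligo does not start with declared adapter {lead}")
    tail = int(cfg["trailing_len"])
    return seq[len(lead) : len(seq) - tail if tail else None]


def variant_report(seq: CodingSequence, sub: CdsSubstitution) -> dict:
    """One-stop per-variant report used by the CLI ``scc`` subcommand."""
    mutant = apply_substitution(seq, sub)
    kind, ctx = classify_variant(seq, mutant)
    report: dict = {
        "sequence_id": seq.id,
        "substitution": sub.hgvs_c,
        "codon_index": codon_index(sub.position),
        "class": kind,
    }
    if ctx is not None:
        n_res, mass_kda = predicted_truncation(mutant, ctx.codon_index)
        report.update(
            {
                "stop_codon": ctx.stop_codon_rna,
                "scc_23nt": ctx.scc_23nt,
                "leakiness_rank": ctx.leakiness_rank,
                "leakiness_label": ctx.leakiness_label,
                "motif_distance": None if GAP in ctx.downstream_10nt[:4] else motif_distance(ctx),
                "near_cognate_candidates": sorted(near_cognate_candidates(ctx.stop_codon)),
                "truncation_residues": n_res,
                "truncation_mass_kda": round(mass_kda, 2),
            }
        )
    return report
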