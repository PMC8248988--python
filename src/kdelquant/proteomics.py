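"""C-terminal ER retrieval-signal extraction, classification and weighted motif matrices.

ER-resident luminal proteins carry a C-terminal tetrapeptide retrieval signal
(canonically x-D-E-L, with the variable "-4" residue x typically K, H or R in
mammals). This module extracts the terminal signal from proteome sequences,
classifies it by the -4 variant, and builds position-probability matrices for
sequence logos weighted either by protein frequency (each protein counts once)
or by cellular abundance (each protein counts in proportion to its copy number
or concentration). It also sums abundance per variant class, e.g. the combined
cellular concentration of all KDEL-bearing proteins versus all HDEL-bearing
ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_VALID_CHARS = set(AMINO_ACIDS) | {"X"}

#: canonical retrieval-signal suffixes: positions -3..-1 of the tetrapeptide
CANONICAL_SUFFIXES = ("DEL",)
#: extended set including the x-E-E-L signals seen on some FKBP-family proteins
EXTENDED_SUFFIXES = ("DEL", "EEL")


class SequenceValidationError(ValueError):
    """Sequence contains characters outside the amino-acid alphabet."""


class SequenceLengthError(ValueError):
    """Sequence shorter than the requested signal window."""


class DegenerateWeightError(ValueError):
    """All abundance weights are zero; a weighted matrix is undefined."""


class MissingWeightError(KeyError):
    """A record has no abundance entry."""


class UnitMismatchError(ValueError):
    """Abundances with different units were mixed in one computation."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional abundance annotation.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        One-letter amino-acid sequence ('X' allowed for unknown residues).
    abundance : float
        Non-negative abundance (copies per cell or concentration).
    unit : str
        Unit of ``abundance``; carried as metadata, never converted.
    source : str
        Dataset label (e.g. the proteome the record came from).
    """

    id: str
    sequence: str
    abundance: float = 0.0
    unit: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence.upper()) - _VALID_CHARS
        if bad:
            raise SequenceValidationError(
                f"{self.id}: illegal sequence characters {sorted(bad)}"
            )
        if self.abundance < 0:
            raise ValueError(f"{self.id}: abundance must be >= 0")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SignalClass:
    """Classified C-terminal signal of one protein.

    ``tetrapeptide`` is the last four residues, ``variant`` the -4 residue,
    ``canonical`` whether positions -3..-1 match one of the accepted suffixes
    (x-D-E-L by default), and ``window`` the last-L-residue string used for
    motif matrices.
    """

    record_id: str
    tetrapeptide: str
    variant: str
    canonical: bool
    window: str


def extract_terminal_signal(
    record: ProteinRecord,
    window_length: int = 6,
    suffixes: Sequence[str] = CANONICAL_SUFFIXES,
) -> SignalClass:
    """Extract and classify the C-terminal retrieval signal of one protein.

    Parameters
    ----------
    record : ProteinRecord
    window_length : int
        Number of C-terminal residues retained for motif analysis (>= 4).
    suffixes : sequence of str
        3-residue suffixes accepted as canonical (default x-D-E-L only).

    Raises
    ------
    SequenceLengthError
        If the sequence is shorter than ``window_length``.
    """
    if window_length < 4:
        raise ValueError("window_length must be >= 4")
    seq = record.sequence
    if len(seq) < window_length:
        raise SequenceLengthError(
            f"{record.id}: sequence length {len(seq)} < window {window_length}"
        )
    tetra = seq[-4:]
    return SignalClass(
        record_id=record.id,
        tetrapeptide=tetra,
        variant=tetra[0],
        canonical=tetra[1:] in set(suffixes),
        window=seq[-window_length:],
    )


def classify_proteome(
    records: Sequence[ProteinRecord],
    window_length: int = 6,
    suffixes: Sequence[str] = CANONICAL_SUFFIXES,
) -> tuple[list[SignalClass], dict[str, int]]:
    """Classify every record and count canonical signals per -4 variant.

    Returns the per-record signal classifications and a Counter-like dict
    mapping variant letter -> number of canonical records; non-canonical
    tails are excluded from the counts.
    """
    if not records:
        raise ValueError("classify_proteome: empty record list")
    signals = [extract_terminal_signal(r, window_length, suffixes) for r in records]
    counts = Counter(s.variant for s in signals if s.canonical)
    return signals, dict(counts)


@dataclass
class WeightedMotifMatrix:
    """Position-probability matrix over a C-terminal window, with information content.

    ``probabilities`` has shape (20, L): rows follow :data:`AMINO_ACIDS`,
    columns run from position -L (leftmost) to -1 (rightmost). Information
    content per column is ``log2(20) + sum_i p_ij log2 p_ij`` in bits (0 for a
    uniform column, log2 20 ~ 4.32 for a one-hot column). No small-sample
    correction is applied.
    """

    window_length: int
    probabilities: np.ndarray
    mode: str
    information_content: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (20, self.window_length):
            raise ValueError(f"probabilities must be 20x{self.window_length}")
        self.probabilities = p
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        self.information_content = np.log2(20.0) + plogp.sum(axis=0)

    @property
    def positions(self) -> list[int]:
        """Column labels -L..-1."""
        return list(range(-self.window_length, 0))

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame (rows = amino acids, columns = positions)."""
        return pd.DataFrame(
            self.probabilities, index=list(AMINO_ACIDS), columns=self.positions
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="aa")


def motif_matrix(
    signals: Sequence[SignalClass],
    weights: Mapping[str, float] | None = None,
    mode: str = "frequency",
) -> WeightedMotifMatrix:
    """Frequency- or abundance-weighted position-probability matrix.

    In ``frequency`` mode every signal gets weight 1; in ``abundance`` mode
    each signal is weighted by ``weights[record_id]``. 'X' residues contribute
    nothing to the 20 probability rows but keep their weight in the column
    normalisation, so a column where X carries weight sums to less than 1 by
    exactly that mass fraction; X-free columns sum to 1. Raises
    :class:`DegenerateWeightError` if all weights vanish.
    """
    if mode not in ("frequency", "abundance"):
        raise ValueError(f"unknown mode {mode!r}")
    if not signals:
        raise ValueError("motif_matrix: no signals")
    L = len(signals[0].window)
    if any(len(s.window) != L for s in signals):
        raise ValueError("all signals must share the same window length")

    if mode == "frequency":
        w = np.ones(len(signals))
    else:
        if weights is None:
            raise ValueError("abundance mode requires weights")
        try:
            w = np.array([float(weights[s.record_id]) for s in signals])
        except KeyError as e:
            raise MissingWeightError(f"no abundance for record {e.args[0]!r}") from e
        if (w < 0).any():
            raise ValueError("negative abundance weight")
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightError("all weights are zero")

    counts = np.zeros((20, L))
    x_mass = np.zeros(L)  # weight carried by 'X' at each position
    for s, wk in zip(signals, w):
        for j, aa in enumerate(s.window):
            if aa == "X":
                x_mass[j] += wk
            else:
                counts[_AA_INDEX[aa], j] += wk
    # X keeps its weight in the denominator only at positions where it occurs
    denom = counts.sum(axis=0) + x_mass
    probs = counts / denom
    return WeightedMotifMatrix(window_length=L, probabilities=probs, mode=mode)


@dataclass
class AbundanceSummary:
    """Summed abundance per canonical -4 variant and requested pairwise ratios."""

    totals: dict[str, float]
    ratios: dict[tuple[str, str], float]
    undefined_ratios: list[tuple[str, str]]
    unit: str = ""

    def to_json_dict(self) -> dict:
        return {
            "unit": self.unit,
            "totals": self.totals,
            "ratios": {f"{a}/{b}": v for (a, b), v in self.ratios.items()},
            "undefined_ratios": [f"{a}/{b}" for a, b in self.undefined_ratios],
        }


def abundance_summary(
    signals: Sequence[SignalClass],
    records: Sequence[ProteinRecord],
    ratio_pairs: Iterable[tuple[str, str]] = (("K", "H"), ("K", "R")),
) -> AbundanceSummary:
    """Sum abundance per canonical variant and form variant/variant ratios.

    Every canonical signal must have a matching record carrying its abundance;
    mixing abundance units raises :class:`UnitMismatchError`. Ratios against an
    empty (zero-total) variant class are flagged as undefined, not computed.
    """
    by_id = {r.id: r for r in records}
    units = {r.unit for r in records if r.unit}
    if len(units) > 1:
        raise UnitMismatchError(f"mixed abundance units: {sorted(units)}")
    totals: dict[str, float] = {}
    for s in signals:
        if not s.canonical:
            continue
        if s.record_id not in by_id:
            raise MissingWeightError(f"no abundance record for {s.record_id!r}")
        totals[s.variant] = totals.get(s.variant, 0.0) + by_id[s.record_id].abundance
    ratios: dict[tuple[str, str], float] = {}
    undefined: list[tuple[str, str]] = []
    for a, b in ratio_pairs:
        tb = totals.get(b, 0.0)
        if tb > 0:
            ratios[(a, b)] = totals.get(a, 0.0) / tb
        else:
            undefined.append((a, b))
    return AbundanceSummary(
        totals=totals,
        ratios=ratios,
        undefined_ratios=undefined,
        unit=units.pop() if units else "",
    )


# ---------------------------------------------------------------- file input


def read_proteome(
    fasta_path, abundance_path=None, source: str = ""
) -> list[ProteinRecord]:
    """Read sequences from FASTA, optionally joining a TSV/CSV abundance table.

    The abundance table needs columns ``id``, ``abundance`` and optionally
    ``unit``; separator is inferred from the file extension.
    """
    abund: dict[str, tuple[float, str]] = {}
    if abundance_path is not None:
        sep = "\t" if str(abundance_path).endswith((".tsv", ".tab")) else ","
        tab = pd.read_csv(abundance_path, sep=sep)
        if not {"id", "abundance"} <= set(tab.columns):
            raise ValueError("abundance table needs columns 'id' and 'abundance'")
        for _, row in tab.iterrows():
            abund[str(row["id"])] = (
                float(row["abundance"]),
                str(row["unit"]) if "unit" in tab.columns else "",
            )
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        a, u = abund.get(rec.id, (0.0, ""))
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), abundance=a, unit=u, source=source)
        )
    return records
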