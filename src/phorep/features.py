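"""Sequence-derived physicochemical features of precursor and mature proteins.

Molecular weight uses average residue masses plus one water; the theoretical
isoelectric point is the unique root of the Henderson-Hasselbalch net-charge
function over the termini and the D, E, C, Y, H, K, R side chains, found by
bisection with the Bjellqvist pKa set (ProtParam's convention). Twin-arginine
(Tat) export signals are detected by a consensus-pattern heuristic in the
N-terminal window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .constants import AVERAGE_RESIDUE_MASS, PKA_BJELLQVIST, PKA_EMBOSS, WATER_MASS
from .io import SequenceRecord

PKA_SETS = {"bjellqvist": PKA_BJELLQVIST, "emboss": PKA_EMBOSS}


@dataclass
class TatMotif:
    """A twin-arginine translocase signal match in the N-terminal window."""

    begin: int  # 1-based
    end: int
    matched: str
    high_confidence: bool


@dataclass
class ProteinFeatureSet:
    protein_id: str
    length: int
    mw_precursor_kda: float
    pi_precursor: float
    signal_length: int | None = None
    mw_mature_kda: float | None = None
    pi_mature: float | None = None
    tat_motif: TatMotif | None = None


def molecular_weight(sequence: str | SequenceRecord) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water.

    ``X`` has no defined mass and raises ``ValueError``.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(seq, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"residue {aa!r} at position {pos} has no defined mass"
            ) from None
    return total


def net_charge(sequence: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH."""
    pka = PKA_SETS[pka_set]
    seq = sequence.upper()
    positive = 0.0
    negative = 0.0
    # termini
    nterm_pka = pka["nterm_by_residue"].get(seq[0], pka["nterm"])
    cterm_pka = pka["cterm_by_residue"].get(seq[-1], pka["cterm"])
    positive += 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    negative += 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa, p in pka["positive"].items():
        n = seq.count(aa)
        if n:
            positive += n / (1.0 + 10 ** (ph - p))
    for aa, p in pka["negative"].items():
        n = seq.count(aa)
        if n:
            negative += n / (1.0 + 10 ** (p - ph))
    return positive - negative


def isoelectric_point(
    sequence: str | SequenceRecord,
    pka_set: str = "bjellqvist",
    tolerance: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection.

    The net-charge function is strictly decreasing in pH and positive at
    pH 0 / negative at pH 14 for any real peptide (the termini always
    ionize), so the root exists and is unique.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, pka_set) <= 0 or net_charge(seq, hi, pka_set) >= 0:
        raise ValueError("net-charge function does not bracket a root")
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def cleave_signal(sequence: str | SequenceRecord, signal_length: int) -> str:
    """Mature sequence after removing the N-terminal signal peptide."""
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence
    if not 0 < signal_length < len(seq):
        raise ValueError(
            f"signal length {signal_length} outside (0, {len(seq)})"
        )
    return seq[signal_length:]


_TAT_STRICT = re.compile(r"[ST]RR.[FGAVML][LITMVF]")
_TAT_RELAXED = re.compile(r"RR")


def find_tat_motif(sequence: str | SequenceRecord, window: int = 45) -> TatMotif | None:
    """First Tat consensus match ([ST]-R-R-x-[FGAVML]-[LITMVF]) in the window.

    Falls back to a bare twin-arginine (RR) match flagged low-confidence;
    returns None when no RR occurs within the window.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else sequence.upper()
    head = seq[:window]
    m = _TAT_STRICT.search(head)
    if m:
        return TatMotif(m.start() + 1, m.end(), m.group(0), high_confidence=True)
    m = _TAT_RELAXED.search(head)
    if m:
        return TatMotif(m.start() + 1, m.end(), m.group(0), high_confidence=False)
    return None


def protein_features(
    record: SequenceRecord,
    signal_length: int | None = None,
    pka_set: str = "bjellqvist",
) -> ProteinFeatureSet:
    """Full feature set for one protein, precursor and (optionally) mature."""
    mw_pre = molecular_weight(record) / 1000.0
    pi_pre = isoelectric_point(record, pka_set)
    features = ProteinFeatureSet(
        protein_id=record.id,
        length=len(record),
        mw_precursor_kda=mw_pre,
        pi_precursor=pi_pre,
        signal_length=signal_length,
        tat_motif=find_tat_motif(record),
    )
    if signal_length is not None:
        mature = cleave_signal(record, signal_length)
        features.mw_mature_kda = molecular_weight(mature) / 1000.0
        features.pi_mature = isoelectric_point(mature, pka_set)
    return features


def features_to_tsv(feature_sets: list[ProteinFeatureSet]) -> str:
    lines = [
        "protein_id\tlength\tsignal_length\tmw_precursor_kda\tmw_mature_kda"
        "\tpi_precursor\tpi_mature\ttat_motif"
    ]
    for f in feature_sets:
        tat = (
            f"{f.tat_motif.matched}@{f.tat_motif.begin}"
            + ("" if f.tat_motif.high_confidence else "(low)")
            if f.tat_motif else ""
        )
        mwm = f"{f.mw_mature_kda:.1f}" if f.mw_mature_kda is not None else ""
        pim = f"{f.pi_mature:.1f}" if f.pi_mature is not None else ""
        lines.append(
            f"{f.protein_id}\t{f.length}\t{f.signal_length if f.signal_length is not None else ''}"
            f"\t{f.mw_precursor_kda:.1f}\t{mwm}\t{f.pi_precursor:.1f}\t{pim}\t{tat}"
        )
    return "\n".join(lines) + "\n"
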