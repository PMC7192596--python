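"""Element subtyping (prophage / ICE) and the domain-disruption assay.

Subtyping scores each element's protein content against curated phage HMM
lists (split into virion and non-virion categories) and an ICE HMM list,
applying printed count/fraction heuristics; double calls resolve to the
composite ICE+Phage (strong phage call) or to ICE (weak phage call).

The domain-disruption assay asks whether integration inactivated the
target gene *without* restoring it.  For each non-t(m)RNA element a 998-bp
window is taken centred at each terminus (outer half chromosomal, inner
half element) and translated in all six frames (12 attLR peptides); the
uninterrupted-site (attB) peptides join the chromosomal halves of the attL
and attR windows in all nine frame combinations on each strand (18 attB
peptides).  Matches spanning the centre crossover position at >= 20 bits
are kept; for the best-scoring domain, attB is said to win — the domain is
disrupted without restoration — when its top attB score is at least
1.1-fold the top attLR score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .engine import revcomp
from .hmm import HmmScorer
from .model import Replicon

__all__ = [
    "TypeCall", "type_ige", "estimate_composition",
    "AttPeptide", "build_att_peptides",
    "Outcome", "DisruptionResult", "disruption_assay",
    "assay_counts", "format_assay_table",
]

#: recall of the subtype heuristics on positive-control sets
DEFAULT_RECALLS = {"phage": 0.982, "ice": 0.752}


@dataclass
class TypeCall:
    phage1: bool
    phage2: bool
    ice1: bool
    ice2: bool
    final: str = "Unknown"


def resolve_type_flags(phage1: bool, phage2: bool, ice1: bool, ice2: bool) -> str:
    """Deterministic resolution of the four subtype flags.

    A strong phage call (phage1) together with any ICE call yields the
    composite ICE+Phage; a weak phage call (phage2) loses to ICE."""
    ice = ice1 or ice2
    if phage1:
        return "ICE+Phage" if ice else "Phage"
    if phage2:
        return "ICE" if ice else "Phage-weak"
    if ice:
        return "ICE"
    return "Unknown"


def type_ige(
    n_proteins: int,
    n_virion: int,
    n_nonvirion: int,
    n_ice: int,
    ige_len: int,
) -> TypeCall:
    """Subtype one element from its protein HMM-hit composition.

    ``n_virion`` / ``n_nonvirion`` are counts of proteins hitting the two
    phage HMM categories; ``n_ice`` counts proteins hitting ICE HMMs.
    Heuristics: Phage1 needs one hit of each phage category; Phage2 one
    phage hit of a single category; ICE1 needs >= 7 ICE hits covering
    >= 15% of proteins; ICE2 >= 2 ICE hits covering >= 12% (< 10 kb) or
    >= 7% (>= 10 kb) of proteins."""
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    frac = n_ice / n_proteins
    phage1 = n_virion >= 1 and n_nonvirion >= 1
    phage2 = (n_virion >= 1 or n_nonvirion >= 1) and not phage1
    ice1 = n_ice >= 7 and frac >= 0.15
    ice2 = n_ice >= 2 and frac >= (0.12 if ige_len < 10_000 else 0.07)
    return TypeCall(
        phage1=phage1, phage2=phage2, ice1=ice1, ice2=ice2,
        final=resolve_type_flags(phage1, phage2, ice1, ice2),
    )


def estimate_composition(
    raw_fractions: Mapping[str, float],
    recalls: Mapping[str, float] = DEFAULT_RECALLS,
) -> dict[str, float]:
    """Correct raw subtype fractions for heuristic recall.

    corrected = raw / recall per type; the remainder is 'unknown'.  If the
    corrected fractions exceed 1 they are renormalized and flagged."""
    out: dict[str, float] = {}
    for key, raw in raw_fractions.items():
        recall = recalls.get(key, 1.0)
        if recall <= 0 or recall > 1:
            raise ValueError(f"recall for {key!r} must be in (0, 1]")
        out[key] = raw / recall
    total = sum(out.values())
    if total > 1.0:
        out = {k: v / total for k, v in out.items()}
        out["renormalized"] = 1.0
        total = 1.0
    out["unknown"] = max(0.0, 1.0 - total)
    return out


# --- domain disruption assay --------------------------------------------------

HALF = 499  # bp on each side of a terminus in the att windows


@dataclass
class AttPeptide:
    seq: str
    kind: str        # "attLR" or "attB"
    label: str       # e.g. "attL+f1", "attB+f0x2"
    center_res: int  # 0-based residue index covering the crossover


class Outcome(str, enum.Enum):
    no_spanning = "no_spanning"
    no_attLR = "no_attLR"
    no_attB = "no_attB"
    attLR_win = "attLR_win"
    attB_win = "attB_win"


@dataclass
class DisruptionResult:
    ige_id: str
    outcome: Outcome
    best_pfam: str = ""
    top_attLR: float = 0.0
    top_attB: float = 0.0
    crossover_pos_in_domain: int = -1


def _translate(dna: str) -> str:
    dna = dna[: len(dna) - len(dna) % 3]
    if not dna:
        return ""
    return str(Seq(dna).translate())


def _frames(window: str, center: int, tag: str) -> list[AttPeptide]:
    """Six-frame translation of a window; the centre residue is the one
    whose codon covers the crossover base (0-based offset ``center``)."""
    peps = []
    for f in range(3):
        pep = _translate(window[f:])
        if pep:
            c = max(0, min((center - f) // 3, len(pep) - 1))
            peps.append(AttPeptide(pep, "attLR", f"{tag}+f{f}", c))
    rc = revcomp(window)
    rc_center = len(window) - 1 - center
    for f in range(3):
        pep = _translate(rc[f:])
        if pep:
            c = max(0, min((rc_center - f) // 3, len(pep) - 1))
            peps.append(AttPeptide(pep, "attLR", f"{tag}-f{f}", c))
    return peps


def build_att_peptides(
    replicon: Replicon,
    left_term: int,
    right_term: int,
    ref_attB_context: Optional[str] = None,
) -> list[AttPeptide]:
    """Construct the 12 attLR and 18 attB peptides for one element.

    attL window: 499 bp of chromosome then 499 bp of element, centred on
    the left terminus; attR mirrored.  attB candidates join the
    chromosomal halves at the DNA level in all nine frame-offset
    combinations per strand, so that whatever the direct-repeat length
    shifted between the flanks, one combination restores the reading frame
    on both sides of the crossover.  Near a linear replicon end the
    windows truncate and are flagged by shorter halves."""
    L, R = left_term, right_term
    l_out = replicon.fetch(L - HALF, L - 1)
    l_in = replicon.fetch(L, L + HALF - 1)
    r_in = replicon.fetch(R - HALF + 1, R)
    r_out = replicon.fetch(R + 1, R + HALF)

    peps: list[AttPeptide] = []
    wL = l_out + l_in
    wR = r_in + r_out
    peps += _frames(wL, len(l_out), "attL")
    peps += _frames(wR, len(r_in), "attR")

    # attB: chromosomal halves joined, forward strand
    for i in range(3):
        for j in range(3):
            dna = l_out[i:] + r_out[j:]
            pep = _translate(dna)
            if pep:
                c = max(0, min((len(l_out) - i - 1) // 3, len(pep) - 1))
                peps.append(AttPeptide(pep, "attB", f"attB+f{i}x{j}", c))
    # reverse strand: the chromosomal half right of attR comes first
    rc_r_out = revcomp(r_out)
    rc_l_out = revcomp(l_out)
    for i in range(3):
        for j in range(3):
            dna = rc_r_out[i:] + rc_l_out[j:]
            pep = _translate(dna)
            if pep:
                c = max(0, min((len(rc_r_out) - i - 1) // 3, len(pep) - 1))
                peps.append(AttPeptide(pep, "attB", f"attB-f{i}x{j}", c))
    return peps


def disruption_assay(
    peptides: Sequence[AttPeptide],
    scorer: HmmScorer,
    ige_id: str = "",
    span_cutoff: float = 20.0,
    win_ratio: float = 1.1,
) -> DisruptionResult:
    """Score all att peptides, keep hits spanning the crossover at or
    above ``span_cutoff`` bits, and compare the best domain's top attB
    score against its top attLR score."""
    spanning: list[tuple[AttPeptide, str, float, int]] = []
    for p in peptides:
        for h in scorer.score(p.seq):
            if h.bitscore < span_cutoff:
                continue
            if not (h.env_start <= p.center_res + 1 <= h.env_end):
                continue
            spanning.append((p, h.pfam, h.bitscore, h.env_start))
    if not spanning:
        return DisruptionResult(ige_id=ige_id, outcome=Outcome.no_spanning)
    best_pfam = max(spanning, key=lambda t: t[2])[1]
    lr = [t for t in spanning if t[1] == best_pfam and t[0].kind == "attLR"]
    bb = [t for t in spanning if t[1] == best_pfam and t[0].kind == "attB"]
    top_lr = max((t[2] for t in lr), default=0.0)
    top_b = max((t[2] for t in bb), default=0.0)
    if not lr:
        outcome = Outcome.no_attLR
    elif not bb:
        outcome = Outcome.no_attB
    elif top_b >= win_ratio * top_lr:
        outcome = Outcome.attB_win
    else:
        outcome = Outcome.attLR_win
    ref = max(bb or lr, key=lambda t: t[2])
    crossover = ref[0].center_res + 1 - ref[3]
    return DisruptionResult(
        ige_id=ige_id, outcome=outcome, best_pfam=best_pfam,
        top_attLR=top_lr, top_attB=top_b,
        crossover_pos_in_domain=crossover,
    )


def assay_counts(results: Sequence[DisruptionResult]) -> dict[str, int]:
    counts = {
        "iges": len(results), "spanning": 0, "no_attLR": 0,
        "no_attB": 0, "attLR_win": 0, "attB_win": 0,
    }
    for r in results:
        if r.outcome is Outcome.no_spanning:
            continue
        counts["spanning"] += 1
        counts[r.outcome.value] += 1
    return counts


def format_assay_table(counts: Mapping[str, int]) -> dict[str, float]:
    """Cohort percentages: spanning as % of elements; the four outcome
    rows as % of spanning.  Values rounded to two decimals."""
    n, s = counts["iges"], counts["spanning"]
    pct = lambda a, b: round(100.0 * a / b, 2) if b else 0.0
    return {
        "spanning_pct": pct(s, n),
        "no_attLR_pct": pct(counts["no_attLR"], s),
        "no_attB_pct": pct(counts["no_attB"], s),
        "attLR_win_pct": pct(counts["attLR_win"], s),
        "attB_win_pct": pct(counts["attB_win"], s),
    }
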