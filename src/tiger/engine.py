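"""Local alignment engines.

Two interchangeable engines produce :class:`AlignmentMatch` records:

* :class:`KmerMatchEngine` — a deterministic, dependency-free seed-and-extend
  local matcher (exact k-mer seeding on diagonals, ungapped X-drop
  extension).  It models substitutions but not indels, which is the regime
  of the synthetic fixtures and of closely related reference genomes.
* :class:`BlastnEngine` — an adapter around the external ``blastn`` binary
  (megablast defaults), parsing tabular output into the same record.

Coordinates are 1-based inclusive.  ``q_start <= q_end`` always; for
``strand == '-'`` the subject coordinates are reported on the forward
subject strand with ``s_start <= s_end`` and the alignment pairs the query
with the reverse complement of that subject interval.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol

__all__ = [
    "AlignmentMatch",
    "Engine",
    "KmerMatchEngine",
    "BlastnEngine",
    "revcomp",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentMatch:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+' or '-'
    length: int
    identity: float  # fraction in [0, 1]

    @property
    def score(self) -> float:
        return self.length * self.identity

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("coordinates must satisfy start <= end")


class Engine(Protocol):
    def search(
        self, query: str, subjects: Mapping[str, str], query_id: str = "query"
    ) -> list[AlignmentMatch]:
        ...


class KmerMatchEngine:
    """Exact k-mer seeded, ungapped X-drop extended local matcher."""

    def __init__(
        self,
        k: int = 16,
        min_len: int = 30,
        max_seed_gap: int = 60,
        xdrop: int = 20,
        mismatch_penalty: int = 3,
    ) -> None:
        self.k = k
        self.min_len = min_len
        self.max_seed_gap = max_seed_gap
        self.xdrop = xdrop
        self.mismatch_penalty = mismatch_penalty

    # -- internals -------------------------------------------------------

    def _index(self, seq: str) -> dict[str, list[int]]:
        k = self.k
        idx: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            idx.setdefault(kmer, []).append(i)
        return idx

    def _extend(
        self, q: str, s: str, qs: int, qe: int, d: int
    ) -> tuple[int, int, int]:
        """Extend the run q[qs:qe] vs s[qs-d:qe-d] both ways, ungapped.

        Returns (start, end, n_ident) on the query, 0-based half-open.
        """
        pen, xdrop = self.mismatch_penalty, self.xdrop
        # leftwards
        best, score = 0, 0
        best_i = qs
        i = qs - 1
        while i >= 0 and i - d >= 0:
            score += 1 if q[i] == s[i - d] else -pen
            if score > best:
                best, best_i = score, i
            if score < best - xdrop:
                break
            i -= 1
        start = best_i
        # rightwards
        best, score = 0, 0
        best_j = qe
        j = qe
        while j < len(q) and j - d < len(s):
            score += 1 if q[j] == s[j - d] else -pen
            if score > best:
                best, best_j = score, j + 1
            if score < best - xdrop:
                break
            j += 1
        end = best_j
        n_ident = sum(1 for x in range(start, end) if q[x] == s[x - d])
        return start, end, n_ident

    def _one_strand(
        self, q: str, s: str, sid: str, qid: str, strand: str, s_len: int
    ) -> list[AlignmentMatch]:
        k = self.k
        idx = self._index(s)
        # seed positions grouped by diagonal d = q_pos - s_pos
        diags: dict[int, list[int]] = {}
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            if "N" in kmer:
                continue
            for j in idx.get(kmer, ()):
                diags.setdefault(i - j, []).append(i)
        out: list[AlignmentMatch] = []
        for d, positions in diags.items():
            positions.sort()
            # chain seeds separated by at most max_seed_gap into runs
            runs: list[tuple[int, int]] = []
            rs = re = positions[0]
            for p in positions[1:]:
                if p - re <= self.max_seed_gap + k:
                    re = p
                else:
                    runs.append((rs, re + k))
                    rs = re = p
            runs.append((rs, re + k))
            covered_to = -1
            for rs, re in runs:
                if re <= covered_to:
                    continue
                start, end, n_ident = self._extend(q, s, rs, re, d)
                covered_to = end
                length = end - start
                if length < self.min_len:
                    continue
                qa, qb = start + 1, end  # 1-based inclusive
                sa, sb = start - d + 1, end - d
                if strand == "-":
                    sa, sb = s_len - sb + 1, s_len - sa + 1
                out.append(
                    AlignmentMatch(
                        query_id=qid, subject_id=sid,
                        q_start=qa, q_end=qb, s_start=sa, s_end=sb,
                        strand=strand, length=length,
                        identity=n_ident / length,
                    )
                )
        # drop matches wholly contained in a better one (seed-collision noise)
        out.sort(key=lambda m: -m.score)
        kept: list[AlignmentMatch] = []
        for m in out:
            if any(
                k2.q_start <= m.q_start and m.q_end <= k2.q_end
                and k2.s_start <= m.s_start and m.s_end <= k2.s_end
                and k2.strand == m.strand
                for k2 in kept
            ):
                continue
            kept.append(m)
        return kept

    # -- public ----------------------------------------------------------

    def search(
        self, query: str, subjects: Mapping[str, str], query_id: str = "query"
    ) -> list[AlignmentMatch]:
        query = query.upper()
        out: list[AlignmentMatch] = []
        for sid, s in subjects.items():
            s = s.upper()
            out.extend(self._one_strand(query, s, sid, query_id, "+", len(s)))
            out.extend(
                self._one_strand(query, revcomp(s), sid, query_id, "-", len(s))
            )
        out.sort(key=lambda m: (m.subject_id, -m.score))
        return out


class BlastnEngine:
    """Adapter invoking external ``blastn`` (default megablast task)."""

    def __init__(self, task: str = "megablast", evalue: float = 1e-5) -> None:
        if shutil.which("blastn") is None:
            raise RuntimeError("blastn not found on PATH")
        self.task = task
        self.evalue = evalue

    def search(
        self, query: str, subjects: Mapping[str, str], query_id: str = "query"
    ) -> list[AlignmentMatch]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            qf, sf = tmp / "q.fa", tmp / "s.fa"
            qf.write_text(f">{query_id}\n{query}\n")
            with open(sf, "w") as fh:
                for sid, seq in subjects.items():
                    fh.write(f">{sid}\n{seq}\n")
            cmd = [
                "blastn", "-task", self.task, "-query", str(qf),
                "-subject", str(sf), "-evalue", str(self.evalue),
                "-outfmt", "6 qseqid sseqid qstart qend sstart send length pident sstrand",
            ]
            res = subprocess.run(cmd, capture_output=True, text=True, check=True)
        out: list[AlignmentMatch] = []
        for line in res.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            qs, qe, ss, se = int(f[2]), int(f[3]), int(f[4]), int(f[5])
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            out.append(
                AlignmentMatch(
                    query_id=f[0], subject_id=f[1],
                    q_start=qs, q_end=qe, s_start=ss, s_end=se,
                    strand=strand, length=int(f[6]), identity=float(f[7]) / 100.0,
                )
            )
        out.sort(key=lambda m: (m.subject_id, -m.score))
        return out
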