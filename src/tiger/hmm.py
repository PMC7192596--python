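"""Protein-domain scorer contract and adapters.

A scorer maps a peptide sequence to a list of :class:`~tiger.model.HmmHit`
(profile name, bitscore in bits, envelope residue coordinates).  Two
adapters are provided:

* :class:`PyhmmerScorer` — profile HMM search via pyhmmer (HMMER3), for
  real Pfam-style profiles or profiles built on the fly from alignments;
* :class:`StubHmmScorer` — a deterministic fixture scorer keyed by exact
  subsequences of a reference domain peptide.  Matches are maximal exact
  substrings of the domain chained collinearly, so a small internal
  deletion (e.g. from a direct-repeat frame join) lowers the score only by
  the missing residues — qualitatively the behaviour of a real profile
  search.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Protocol, Sequence

from .model import HmmHit

__all__ = ["HmmScorer", "StubHmmScorer", "PyhmmerScorer", "hmm_from_seqs"]


class HmmScorer(Protocol):
    def score(self, peptide: str, subject_id: str = "pep") -> list[HmmHit]:
        ...


class StubHmmScorer:
    """Score peptides against literal domain peptides.

    For each named domain, maximal exact substring matches (>= ``min_seed``
    residues) between domain and peptide are found and chained in
    collinear order; the bitscore is ``bits_per_residue`` times the number
    of chained matching residues.  The envelope is the peptide span of the
    chain, and hits are reported with envelope coordinates 1-based."""

    def __init__(
        self,
        domains: Mapping[str, str],
        bits_per_residue: float = 2.0,
        min_seed: int = 8,
    ) -> None:
        self.domains = dict(domains)
        self.bits_per_residue = bits_per_residue
        self.min_seed = min_seed

    def _segments(self, dom: str, pep: str) -> list[tuple[int, int, int]]:
        """Maximal exact matches as (dom_pos, pep_pos, length), 0-based."""
        segs = []
        n, m = len(dom), len(pep)
        # seed on min_seed-mers of the domain
        index: dict[str, list[int]] = {}
        k = self.min_seed
        for i in range(n - k + 1):
            index.setdefault(dom[i : i + k], []).append(i)
        seen: set[tuple[int, int]] = set()
        for j in range(m - k + 1):
            for i in index.get(pep[j : j + k], ()):
                d = j - i
                if (d, i) in seen:
                    continue
                a, b = i, j
                while a > 0 and b > 0 and dom[a - 1] == pep[b - 1]:
                    a -= 1
                    b -= 1
                e = i + k
                f = j + k
                while e < n and f < m and dom[e] == pep[f]:
                    e += 1
                    f += 1
                for x in range(a, e - k + 1):
                    seen.add((d, x))
                segs.append((a, b, e - a))
        return segs

    def score(self, peptide: str, subject_id: str = "pep") -> list[HmmHit]:
        hits: list[HmmHit] = []
        for name, dom in self.domains.items():
            segs = self._segments(dom, peptide)
            if not segs:
                continue
            # chain collinear segments (increasing in both sequences)
            segs.sort(key=lambda s: (s[1], s[0]))
            best_len = [s[2] for s in segs]
            back = [-1] * len(segs)
            for x in range(len(segs)):
                for y in range(x):
                    if (
                        segs[y][0] + segs[y][2] <= segs[x][0]
                        and segs[y][1] + segs[y][2] <= segs[x][1]
                        and best_len[y] + segs[x][2] > best_len[x]
                    ):
                        best_len[x] = best_len[y] + segs[x][2]
                        back[x] = y
            x = max(range(len(segs)), key=lambda i: best_len[i])
            total = best_len[x]
            chain = []
            while x >= 0:
                chain.append(segs[x])
                x = back[x]
            chain.reverse()
            env_start = chain[0][1] + 1
            env_end = chain[-1][1] + chain[-1][2]
            hits.append(
                HmmHit(
                    subject_id=subject_id, pfam=name,
                    bitscore=total * self.bits_per_residue,
                    env_start=env_start, env_end=env_end,
                )
            )
        hits.sort(key=lambda h: -h.bitscore)
        return hits


def hmm_from_seqs(name: str, seqs: Sequence[str]):
    """Build a profile HMM from equal-length aligned peptides (pyhmmer)."""
    import pyhmmer

    abc = pyhmmer.easel.Alphabet.amino()
    msa = pyhmmer.easel.TextMSA(
        name=name.encode(),
        sequences=[
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=s)
            for i, s in enumerate(seqs)
        ],
    )
    builder = pyhmmer.plan7.Builder(abc)
    background = pyhmmer.plan7.Background(abc)
    hmm, _, _ = builder.build_msa(msa.digitize(abc), background)
    return hmm


class PyhmmerScorer:
    """Profile HMM search via pyhmmer; top domain per profile per peptide."""

    def __init__(self, hmms: Iterable) -> None:
        self.hmms = list(hmms)

    def score(self, peptide: str, subject_id: str = "pep") -> list[HmmHit]:
        import pyhmmer

        abc = pyhmmer.easel.Alphabet.amino()
        seq = pyhmmer.easel.TextSequence(
            name=subject_id.encode(), sequence=peptide.replace("*", "X")
        ).digitize(abc)
        hits_out: list[HmmHit] = []
        for tophits in pyhmmer.hmmsearch(self.hmms, [seq], E=10.0):
            query_name = tophits.query.name.decode()
            for hit in tophits:
                for dom in hit.domains:
                    hits_out.append(
                        HmmHit(
                            subject_id=subject_id,
                            pfam=query_name,
                            bitscore=float(dom.score),
                            env_start=dom.env_from,
                            env_end=dom.env_to,
                        )
                    )
        hits_out.sort(key=lambda h: -h.bitscore)
        return hits_out
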