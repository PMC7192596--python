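"""Readers and writers for genomes, annotations, hit tables and call tables.

Formats:

* genomes / reference collections: (multi-)FASTA via Biopython;
* gene features: GFF3 (via :mod:`gffutils`) or a tabular feature list
  (TSV with columns ``id, replicon_id, start, end, strand, klass[, name]``);
* per-protein HMM hits: TSV with columns
  ``subject_id, pfam, bitscore, env_start, env_end``;
* call tables: TSV, see :data:`CALL_COLUMNS`.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import GeneClass, GeneFeature, GenomeRecord, HmmHit, Replicon, Topology

CALL_COLUMNS = [
    "genome_id",
    "replicon",
    "attL_start",
    "attL_end",
    "attR_start",
    "attR_end",
    "strand",
    "seed_gene",
    "support",
    "fp_score",
    "type",
    "target",
    "name",
]

_KLASS_ALIASES = {
    "y-int": GeneClass.Y_INT,
    "yint": GeneClass.Y_INT,
    "s-int": GeneClass.S_INT,
    "s-core": GeneClass.S_CORE,
    "dde": GeneClass.DDE,
    "xer": GeneClass.XER,
    "inti": GeneClass.INTI,
    "trna": GeneClass.TRNA,
    "tmrna": GeneClass.TMRNA,
    "rrna": GeneClass.RRNA,
    "other-rna": GeneClass.OTHER_RNA,
    "ncrna": GeneClass.OTHER_RNA,
    "cds": GeneClass.CDS,
}


def parse_gene_class(text: str) -> GeneClass:
    try:
        return _KLASS_ALIASES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown gene class {text!r}") from None


def read_fasta(path: os.PathLike | str) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered ``{id: sequence}`` map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _features_from_gff3(path: os.PathLike | str) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[GeneFeature] = []
    for f in db.all_features():
        if f.featuretype in ("region", "source"):
            continue
        attrs = {k.lower(): v for k, v in f.attributes.items()}
        if "gene_class" in attrs:
            klass = parse_gene_class(attrs["gene_class"][0])
        elif f.featuretype in ("tRNA", "tmRNA", "rRNA", "ncRNA"):
            klass = parse_gene_class(f.featuretype)
        else:
            klass = GeneClass.CDS
        name = attrs.get("name", [""])[0] or attrs.get("isotype", [""])[0]
        fid = f.id or attrs.get("id", [f"{f.seqid}:{f.start}-{f.end}"])[0]
        feats.append(
            GeneFeature(
                id=fid, replicon_id=f.seqid, start=f.start, end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                klass=klass, name=name,
            )
        )
    return feats


def _features_from_tsv(path: os.PathLike | str) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "replicon_id", "start", "end", "strand", "klass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        feats.append(
            GeneFeature(
                id=row.id, replicon_id=row.replicon_id,
                start=int(row.start), end=int(row.end), strand=row.strand,
                klass=parse_gene_class(row.klass),
                name=getattr(row, "name_", "") or getattr(row, "gene_name", "") or "",
            )
        )
    return feats


def load_genome(
    fasta_path: os.PathLike | str,
    annotation_path: os.PathLike | str | None = None,
    genome_id: str | None = None,
    topology: Topology = Topology.circular,
    kingdom: str = "Bacteria",
    genetic_code: int = 11,
) -> GenomeRecord:
    """Load a genome FASTA plus its annotation into a :class:`GenomeRecord`.

    The annotation may be GFF3 (``.gff``/``.gff3``) or a tabular feature
    list.  Replicon ids in the annotation must match the FASTA; a feature
    referencing an unknown replicon or exceeding its bounds is a hard error.
    """
    seqs = read_fasta(fasta_path)
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")
    replicons = [Replicon(id=k, seq=v, topology=topology) for k, v in seqs.items()]
    feats: list[GeneFeature] = []
    if annotation_path is not None:
        suffix = str(annotation_path).lower()
        if suffix.endswith((".gff", ".gff3")):
            feats = _features_from_gff3(annotation_path)
        else:
            feats = _features_from_tsv(annotation_path)
    gid = genome_id or os.path.splitext(os.path.basename(str(fasta_path)))[0]
    return GenomeRecord(
        genome_id=gid, replicons=replicons, features=feats,
        genetic_code=genetic_code, kingdom=kingdom,
    )


def read_hmm_hits(path: os.PathLike | str) -> list[HmmHit]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HmmHit(
                subject_id=row.subject_id, pfam=row.pfam,
                bitscore=float(row.bitscore),
                env_start=int(getattr(row, "env_start", 1)),
                env_end=int(getattr(row, "env_end", 1)),
            )
        )
    return hits


# --- integrase classification -------------------------------------------------

#: HMM names with a special meaning for recombinase classification
PHAGE_INTEGRASE = "Phage_integrase"
RESOLVASE = "Resolvase"
RECOMBINASE = "Recombinase"
XER_PROFILES = frozenset({"Xer_C", "Xer_D", "XerC", "XerD"})
INTI_PROFILE = "intI_Cterm"

#: global bitscore floor applied when a profile has no gathering cutoff
DEFAULT_BIT_FLOOR = 20.0


def classify_integrases(
    features: Sequence[GeneFeature],
    hmm_hits: Iterable[HmmHit],
    dde_hmms: frozenset[str] | set[str] = frozenset(),
    bit_floor: float = DEFAULT_BIT_FLOOR,
) -> list[GeneFeature]:
    """Assign recombinase gene classes from per-protein HMM hits.

    Rules (one class per gene):

    * ``Phage_integrase`` hit -> Y-Int, unless an Xer-subfamily or
      ``intI_Cterm`` hit reclassifies it as Xer / IntI (housekeeping roles,
      excluded from seeding);
    * ``Resolvase`` AND ``Recombinase`` hits -> S-Int;
    * ``Resolvase`` only -> S-Core;
    * a hit to any profile in ``dde_hmms`` -> DDE transposase;
    * genes with both ``Phage_integrase`` and ``Resolvase`` hits are classed
      by the higher-scoring family.

    Unhit protein genes keep their existing class (normally CDS).  RNA genes
    are never reclassified.
    """
    by_gene: dict[str, dict[str, float]] = {}
    for h in hmm_hits:
        if h.bitscore < bit_floor:
            continue
        d = by_gene.setdefault(h.subject_id, {})
        if h.pfam not in d or h.bitscore > d[h.pfam]:
            d[h.pfam] = h.bitscore

    out: list[GeneFeature] = []
    for f in features:
        if f.klass is not GeneClass.CDS:
            out.append(f)
            continue
        hits = by_gene.get(f.id, {})
        klass = f.klass
        y_score = hits.get(PHAGE_INTEGRASE)
        res_score = hits.get(RESOLVASE)
        if y_score is not None and res_score is not None:
            # multi-domain oddity: class by best-scoring family
            if y_score >= res_score:
                res_score = None
            else:
                y_score = None
        if y_score is not None:
            if XER_PROFILES & hits.keys():
                klass = GeneClass.XER
            elif INTI_PROFILE in hits:
                klass = GeneClass.INTI
            else:
                klass = GeneClass.Y_INT
        elif res_score is not None:
            klass = (
                GeneClass.S_INT if RECOMBINASE in hits else GeneClass.S_CORE
            )
        elif dde_hmms & hits.keys():
            klass = GeneClass.DDE
        top = max(hits.items(), key=lambda kv: kv[1]) if hits else None
        out.append(
            GeneFeature(
                id=f.id, replicon_id=f.replicon_id, start=f.start, end=f.end,
                strand=f.strand, klass=klass, top_pfam=top, name=f.name,
            )
        )
    return out


# --- call tables --------------------------------------------------------------

def write_call_table(rows: list[dict], path: os.PathLike | str) -> None:
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_call_table(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("attL_start", "attL_end", "attR_start", "attR_end", "support"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df
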