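"""End-to-end convenience: map seeds, resolve, type targets, name calls."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .engine import Engine, KmerMatchEngine
from .mapper import MapperConfig, RawCall, map_genome
from .metrics import support_ratio_filter
from .model import GenomeRecord, INT_SEED_CLASSES, SeedMode
from .resolve import IgeCall, assign_target, name_ige, resolve

__all__ = ["run_pipeline"]


def run_pipeline(
    genome: GenomeRecord,
    refdb: Mapping[str, str],
    islander_calls: Sequence[IgeCall] = (),
    mode: str = "tiger",
    engine: Optional[Engine] = None,
    config: Optional[MapperConfig] = None,
    is_db: Optional[Mapping[str, str]] = None,
    is_filter: bool = True,
    fp_score_fn=None,
    fp_cutoff: Optional[float] = None,
) -> tuple[list[IgeCall], list[RawCall]]:
    """Map every integrase seed, screen seeds by support ratio, resolve
    tandems/overlaps, then assign attB target types and names.

    Returns (resolved calls, raw calls)."""
    engine = engine or KmerMatchEngine()
    raw = map_genome(
        genome, refdb, mode=SeedMode.IGE, config=config, engine=engine,
        is_db=is_db, is_filter=is_filter,
    )
    by_seed: dict[str, list[RawCall]] = {}
    for c in raw:
        by_seed.setdefault(c.seed.gene.id, []).append(c)
    rejected = support_ratio_filter(by_seed)
    int_features = [f for f in genome.features if f.klass in INT_SEED_CLASSES]
    calls = resolve(
        raw,
        islander_calls=list(islander_calls),
        mode=mode,
        int_features=int_features,
        fp_score_fn=fp_score_fn,
        fp_cutoff=fp_cutoff,
        rejected_seeds=rejected,
    )
    for c in calls:
        c.target = assign_target(c, genome.features)
        c.name = name_ige(c, genome.genome_id)
    return calls, raw
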