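"""drugrank: genetics-led drug repurposing analysis.

Gene-level evidence ranking from common- and rare-variant association
statistics, rank fusion (raw/scaled median), Cauchy aggregation of
transcript burden p-values, preranked gene-set enrichment against drug
class and mechanism-of-action gene sets, transcriptomic enrichment, and
clinical-tractability scoring.
"""

from . import (
    cauchy,
    enrichment,
    expression,
    geneset_io,
    pipeline,
    rank_engine,
    synthetic,
    tractability,
)

__version__ = "0.1.0"

__all__ = [
    "cauchy",
    "enrichment",
    "expression",
    "geneset_io",
    "pipeline",
    "rank_engine",
    "synthetic",
    "tractability",
]
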