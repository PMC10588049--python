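"""Gene-level enrichment from peak-level differential accessibility.

Peaks are linked to genes by a precomputed table (peak_id, gene_id[,
score]). A default normal-mixture prior is fitted once to ALL (peak, topic)
estimates; then for each gene and topic the mixture weights are refitted on
the gene's linked peaks over the same scale grid, with a
Dirichlet(1.01 + n0 * w_default) weights prior pulling the refit toward the
default weights. The reported log Bayes factor is the marginal
log-likelihood ratio of the refit prior against the point-mass-at-zero
null.

The DE input here is expected to be unshrunk (global shrinkage skipped);
the per-gene shrinkage below is the only shrinkage applied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from . import shrinkage as shr

logger = logging.getLogger(__name__)

__all__ = [
    "PeakGeneLinks",
    "GeneEnrichResult",
    "gene_enrichment",
    "parse_peak_id",
    "export_bed",
]

_PEAK_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass
class PeakGeneLinks:
    """Deduplicated (peak_id, gene_id) pairs with an optional link score."""

    table: "object"  # pandas.DataFrame with columns peak_id, gene_id[, score]

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        if not {"peak_id", "gene_id"} <= cols:
            raise ValueError("links table needs peak_id and gene_id columns")
        self.table = self.table.drop_duplicates(
            subset=["peak_id", "gene_id"]
        ).reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path: str) -> "PeakGeneLinks":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if "peak_id" not in df.columns:
            df.columns = ["peak_id", "gene_id", "score"][: len(df.columns)]
        return cls(df)


@dataclass
class GeneEnrichResult:
    """Per (gene, topic) rows: log_bf, mean_lelfc (NaN when no linked peak
    passes lfsr < 0.05), n_peaks, n_signif_peaks."""

    table: "object"

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def gene_enrichment(
    de_table,
    links: PeakGeneLinks,
    n0: float = 20.0,
    default_prior: shr.ShrinkPrior | None = None,
    lfsr_cutoff: float = 0.05,
) -> GeneEnrichResult:
    """Aggregate peak-level LFC estimates to per-gene enrichment statistics.

    ``de_table`` is the long-format DE table (columns feature_id, topic,
    postmean, se). The default prior, if not supplied, is fitted once on all
    (peak, topic) estimates with normal components.
    """
    import pandas as pd

    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    de = de_table.table if hasattr(de_table, "table") else de_table
    de = de.dropna(subset=["postmean", "se"])
    de = de[de["se"] > 0]
    beta_all = de["postmean"].to_numpy(dtype=float)
    se_all = de["se"].to_numpy(dtype=float)
    if default_prior is None:
        default_prior = shr.fit_mixture_prior(beta_all, se_all, family="normal")
    scales = default_prior.scales
    alpha = 1.01 + n0 * default_prior.weights

    peak_rows = {
        (fid, int(t)): i
        for i, (fid, t) in enumerate(zip(de["feature_id"], de["topic"]))
    }
    topics = sorted(de["topic"].unique())
    genes = links.table.groupby("gene_id")["peak_id"].apply(list)

    rows = []
    n_skipped = 0
    for gene, peaks in genes.items():
        for k in topics:
            idx = [peak_rows[(p, k)] for p in peaks if (p, k) in peak_rows]
            if not idx:
                n_skipped += 1
                continue
            beta = beta_all[idx]
            se = se_all[idx]
            prior = shr.fit_mixture_prior(
                beta, se, family="normal", weights_prior=alpha, scales=scales
            )
            res = shr.shrink_estimates(beta, se, prior)
            logbf = shr.log_lr(beta, se, prior)
            sig = res.lfsr < lfsr_cutoff
            mean_lelfc = float(res.postmean[sig].mean()) if sig.any() else float("nan")
            rows.append(
                {
                    "gene_id": gene,
                    "topic": k,
                    "log_bf": logbf,
                    "mean_lelfc": mean_lelfc,
                    "n_peaks": len(idx),
                    "n_signif_peaks": int(sig.sum()),
                }
            )
    if n_skipped:
        logger.info("gene_enrichment: skipped %d (gene, topic) pairs with no "
                    "resolvable linked peaks", n_skipped)
    return GeneEnrichResult(pd.DataFrame(rows))


def parse_peak_id(peak_id: str):
    """Parse "chr:start-end" (0-based half-open); returns (chrom, start, end)."""
    mt = _PEAK_RE.match(peak_id)
    if mt is None:
        raise ValueError(f"cannot parse peak id {peak_id!r}")
    return mt["chrom"], int(mt["start"]), int(mt["end"])


def export_bed(de_table, path: str, pvalue_cutoff: float = 0.05) -> None:
    """Write peaks with unmoderated p-value below the cutoff as BED lines.

    Peak ids must be "chr:start-end" strings. Rows whose ids do not parse
    are skipped with a warning.
    """
    de = de_table.table if hasattr(de_table, "table") else de_table
    hits = de[de["pvalue"] < pvalue_cutoff]
    seen = set()
    n_bad = 0
    with open(path, "w") as fh:
        for pid in hits["feature_id"]:
            if pid in seen:
                continue
            seen.add(pid)
            try:
                chrom, start, end = parse_peak_id(pid)
            except ValueError:
                n_bad += 1
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{pid}\n")
    if n_bad:
        logger.warning("export_bed: %d peak ids did not parse as chr:start-end",
                       n_bad)
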