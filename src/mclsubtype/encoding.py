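"""Integer scoring of genetic lesions and assembly of the lesion matrix.

Somatic lesions of heterogeneous origin (nonsilent mutations, copy-number
deletions/amplifications, IGHV somatic-hypermutation status) are encoded on
a common {0, 1, 2} integer scale so that they can be factorized together:

* nonsilent mutation present            -> 1
* IGHV mutated                          -> 2
* deletion,  1.0 <= CN <= 1.7 copies    -> 1  (low level)
* deletion,  CN < 1.0 copies            -> 2  (high level)
* amplification, 2.3 <= CN <= 3.7       -> 1  (low level)
* amplification, CN > 3.7 copies        -> 2  (high level)

Copy number in the open gap (1.7, 2.3) is treated as diploid-neutral and
scores 0 for both lesion kinds.  A gene hit by both a mutation and a
deletion contributes two distinct columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants

logger = logging.getLogger(__name__)

LESION_KINDS = ("mutation", "del", "amp", "IGHV")

#: Mutation classes that do not alter the protein and therefore score 0.
SILENT_CLASSES = frozenset(
    {"silent", "synonymous", "synonymous_variant", "igr", "intron", "utr", "5'utr", "3'utr"}
)


@dataclass
class LesionMatrix:
    """Samples x lesions integer score matrix with per-lesion metadata.

    ``scores`` is a DataFrame indexed by sample id with one column per
    lesion; every entry is in {0, 1, 2}.  ``lesion_meta`` maps lesion name
    to its kind (one of :data:`LESION_KINDS`).
    """

    scores: pd.DataFrame
    lesion_meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size and not np.isin(vals, (0, 1, 2)).all():
            bad = sorted(set(np.unique(vals)) - {0, 1, 2})
            raise ValueError(f"lesion scores must be in {{0,1,2}}; found {bad}")
        unknown = {k for k in self.lesion_meta.values() if k not in LESION_KINDS}
        if unknown:
            raise ValueError(f"unknown lesion kinds: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def lesions(self) -> list[str]:
        return list(self.scores.columns)

    def binarized(self) -> pd.DataFrame:
        """Presence/absence view: any positive score counts as present."""
        return (self.scores > 0).astype(int)


def score_mutation(present: bool) -> int:
    """Score a nonsilent mutation call: present -> 1, absent -> 0."""
    return constants.MUTATION_SCORE if present else 0


def score_ighv(status: str | None, *, missing_policy: str = "error") -> int:
    """Score IGHV somatic-hypermutation status: mutated -> 2, unmutated -> 0.

    ``missing_policy`` governs samples with unknown status: ``"error"``
    raises, ``"zero"`` scores 0 with a warning (the sample is retained).
    """
    if status is None or (isinstance(status, float) and np.isnan(status)):
        if missing_policy == "zero":
            warnings.warn("missing IGHV status imputed as unmutated (score 0)", stacklevel=2)
            return 0
        raise ValueError("IGHV status missing and missing_policy='error'")
    status = str(status).strip().lower()
    if status == "mutated":
        return constants.IGHV_MUTATED_SCORE
    if status == "unmutated":
        return 0
    raise ValueError(f"IGHV status must be 'mutated' or 'unmutated', got {status!r}")


def score_cn(absolute_cn: float, kind: str) -> int:
    """Score an absolute copy-number value for a deletion or amplification column.

    Boundaries are applied exactly as printed: closed where the rule prints
    "<=" (CN=1.0 and CN=1.7 are low-level deletion; CN=2.3 and CN=3.7 are
    low-level amplification) and open where it prints "<"/">".
    """
    if absolute_cn < 0:
        raise ValueError(f"absolute copy number must be >= 0, got {absolute_cn}")
    if kind == "del":
        if absolute_cn < constants.DEL_HIGH_CEILING:
            return 2
        if absolute_cn <= constants.DEL_LOW_CEILING:
            return 1
        return 0
    if kind == "amp":
        if absolute_cn > constants.AMP_HIGH_FLOOR:
            return 2
        if absolute_cn >= constants.AMP_LOW_FLOOR:
            return 1
        return 0
    raise ValueError(f"kind must be 'del' or 'amp', got {kind!r}")


def _is_nonsilent(variant_class: str) -> bool:
    return str(variant_class).strip().lower() not in SILENT_CLASSES


def select_recurrent(
    mutations: pd.DataFrame,
    cn_regions: pd.DataFrame | None = None,
    *,
    n_samples: int | None = None,
    mutation_freq: float = constants.MUTATION_RECURRENCE_FREQ,
    scna_freq: float = constants.SCNA_RECURRENCE_FREQ,
    scna_q: float = constants.SCNA_Q_CUTOFF,
    mode: str = "clustering",
) -> list[str]:
    """Select lesions that pass the recurrence filters.

    ``mutations`` is MAF-like with columns Sample, Gene, Variant_Class.
    ``cn_regions`` summarises one row per region with columns Region,
    Frequency and Q (GISTIC q-values are inputs, never computed here).

    ``mode="clustering"`` applies the clustering-entry rule: gene mutation
    frequency >= 5% plus CN regions at frequency >= 10% with q <= 0.1.
    ``mode="catalogue"`` applies the recurrent-gene reporting rule instead
    (mutated in > 5 samples AND frequency > 3%) and ignores CN regions.
    """
    if mutations.empty and (cn_regions is None or cn_regions.empty):
        raise ValueError("empty cohort: no mutations or CN regions supplied")
    if n_samples is None:
        n_samples = mutations["Sample"].nunique()
    if n_samples == 0:
        raise ValueError("empty cohort: zero samples")

    nonsilent = mutations[mutations["Variant_Class"].map(_is_nonsilent)]
    per_gene = nonsilent.groupby("Gene")["Sample"].nunique()
    freq = per_gene / n_samples

    if mode == "catalogue":
        keep = per_gene[
            (per_gene > constants.CATALOGUE_MIN_SAMPLES) & (freq > constants.CATALOGUE_MIN_FREQ)
        ]
        return sorted(keep.index)
    if mode != "clustering":
        raise ValueError(f"mode must be 'clustering' or 'catalogue', got {mode!r}")

    selected = sorted(freq[freq >= mutation_freq].index)
    if cn_regions is not None and not cn_regions.empty:
        ok = cn_regions[(cn_regions["Frequency"] >= scna_freq) & (cn_regions["Q"] <= scna_q)]
        selected += sorted(ok["Region"])
    return selected


def build_lesion_matrix(
    mutations: pd.DataFrame,
    cn_calls: pd.DataFrame | None = None,
    ighv: pd.Series | None = None,
    *,
    sample_ids: list[str] | None = None,
    genes: list[str] | None = None,
    region_kinds: dict[str, str] | None = None,
    ighv_missing_policy: str = "zero",
) -> LesionMatrix:
    """Assemble the integer lesion matrix from raw calls.

    Parameters
    ----------
    mutations:
        MAF-like frame (Sample, Gene, Variant_Class, ...). Silent classes
        are dropped before scoring.
    cn_calls:
        Long frame (Sample, Region, AbsoluteCN), one row per sample/region.
    ighv:
        Per-sample status series ('mutated'/'unmutated'), indexed by sample.
    sample_ids:
        Row universe; defaults to the union of samples seen in the inputs.
    genes:
        Mutation columns to emit; defaults to all genes with a nonsilent call.
    region_kinds:
        Maps region name -> 'del' or 'amp'. Required when cn_calls is given.
    """
    if sample_ids is None:
        ids: set[str] = set(mutations["Sample"]) if not mutations.empty else set()
        if cn_calls is not None and not cn_calls.empty:
            ids |= set(cn_calls["Sample"])
        if ighv is not None:
            ids |= set(ighv.index)
        sample_ids = sorted(ids)

    columns: dict[str, np.ndarray] = {}
    meta: dict[str, str] = {}
    idx = pd.Index(sample_ids, name="Sample")

    nonsilent = mutations[mutations["Variant_Class"].map(_is_nonsilent)]
    if genes is None:
        genes = sorted(nonsilent["Gene"].unique())
    hit = nonsilent.groupby("Gene")["Sample"].agg(set)
    for gene in genes:
        carriers = hit.get(gene, set())
        columns[gene] = np.array([score_mutation(s in carriers) for s in sample_ids])
        meta[gene] = "mutation"

    if cn_calls is not None and not cn_calls.empty:
        if region_kinds is None:
            raise ValueError("region_kinds required when cn_calls are supplied")
        for region, sub in cn_calls.groupby("Region"):
            kind = region_kinds.get(region)
            if kind is None:
                raise ValueError(f"no kind (del/amp) declared for region {region!r}")
            cn = sub.set_index("Sample")["AbsoluteCN"]
            columns[region] = np.array(
                [score_cn(float(cn[s]), kind) if s in cn.index else 0 for s in sample_ids]
            )
            meta[region] = kind

    if ighv is not None:
        columns["IGHV"] = np.array(
            [
                score_ighv(ighv.get(s), missing_policy=ighv_missing_policy)
                for s in sample_ids
            ]
        )
        meta["IGHV"] = "IGHV"

    scores = pd.DataFrame(columns, index=idx, dtype=int)
    return LesionMatrix(scores=scores, lesion_meta=meta)
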