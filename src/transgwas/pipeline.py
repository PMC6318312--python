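"""End-to-end glue: meta-analysis -> dissection -> enrichment -> fine-mapping.

These helpers wire the stage modules together for a whole panel of studies:
they carve per-locus aligned Z/N arrays out of study tables, run the
iterative conditional dissection at every locus, assemble per-signal Bayes
factors over the locus variant universe, fit the annotation-enrichment model
and fine-map every signal under the joint prior.  Each stage remains usable
on its own; this module only sequences them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import finemap as fm
from .meta import Locus, define_loci, meta_analyse
from .signals import LocusData, SignalSet, dissect_locus, index_variants
from .sumstats import AnnotationTrack, LDMatrix, StudySumStats, annotate_variants

__all__ = ["LocusAnalysis", "PanelAnalysis", "build_locus_data", "analyse_panel"]


def build_locus_data(
    studies: list[StudySumStats],
    locus: Locus,
    ld_by_ancestry: dict[str, LDMatrix],
) -> LocusData:
    """Align per-study Z and N arrays over the variants of one locus.

    The variant universe is the union of variants inside the locus across
    studies, ordered by position; each study's LD reference is its
    ancestry-matched matrix restricted to that universe (variants absent
    from the reference keep zero correlation with the rest, a conservative
    fallback).
    """
    frames = []
    for s, ss in enumerate(studies):
        t = ss.table
        inside = t[(t["chrom"] == locus.chrom) & t["pos"].between(locus.start, locus.end)]
        frames.append(inside.assign(_study=s))
    longf = pd.concat(frames, ignore_index=True)
    variants = (
        longf[["chrom", "pos", "effect_allele", "other_allele"]]
        .drop_duplicates()
        .sort_values(["pos", "effect_allele"])
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(variants[["pos", "effect_allele"]])
    m = len(variants)
    k = len(studies)
    z = np.full((k, m), np.nan)
    n = np.full((k, m), np.nan)
    for s in range(k):
        sub = longf[longf["_study"] == s]
        col = key.get_indexer(pd.MultiIndex.from_frame(sub[["pos", "effect_allele"]]))
        z[s, col] = (sub["beta"] / sub["se"]).to_numpy()
        n[s, col] = sub["n"].to_numpy()
    ld: dict[int, LDMatrix] = {}
    for s, ss in enumerate(studies):
        ref = ld_by_ancestry[ss.ancestry_group]
        ref_key = pd.MultiIndex.from_frame(
            ref.variants.assign(pos=ref.variants["pos"].astype(np.int64))[
                ["pos", "effect_allele"]
            ]
        )
        idx = ref_key.get_indexer(key)
        r = np.eye(m)
        found = np.flatnonzero(idx >= 0)
        r[np.ix_(found, found)] = ref.r[np.ix_(idx[found], idx[found])]
        ld[s] = LDMatrix(variants, r, ss.ancestry_group)
    return LocusData(variants, [s.study_id for s in studies], z, n, ld)


@dataclass
class LocusAnalysis:
    locus: Locus
    data: LocusData
    signal_set: SignalSet
    lead_index: int


@dataclass
class PanelAnalysis:
    meta: pd.DataFrame
    run_log: dict
    loci: list[LocusAnalysis]
    signal_abfs: list = field(default_factory=list)
    z_by_signal: list = field(default_factory=list)
    enrichment_model: "enr.EnrichmentModel | None" = None
    finemap_results: list = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        return len(self.signal_abfs)


def analyse_panel(
    studies: list[StudySumStats],
    ld_by_ancestry_locus,
    tracks: list[AnnotationTrack],
    p_threshold: float = 5e-8,
    p_locuswide: float = 1e-5,
    mass: float = 0.99,
    gc_meta_level: bool = True,
    forward_selection: bool = True,
) -> PanelAnalysis:
    """Run the full summary-statistics pipeline over a panel of studies.

    ``ld_by_ancestry_locus`` is a callable mapping a :class:`Locus` to the
    per-ancestry LD references covering it.  Stages: trans-ethnic Stouffer
    meta-analysis with genomic control, locus definition, per-locus signal
    dissection with leave-one-out index variants, per-signal Bayes factors
    (leave-one-out conditional Z at multi-signal loci, marginal meta Z
    otherwise), per-category forward selection plus joint enrichment fit,
    and annotation-informed fine-mapping of every signal.
    """
    meta, log = meta_analyse(studies, gc_meta_level=gc_meta_level)
    lam = log["lambda_meta"] if gc_meta_level else 1.0
    loci = define_loci(meta, p_threshold=p_threshold)

    analyses: list[LocusAnalysis] = []
    signal_abfs, z_by_signal, signal_pos = [], [], []
    for li, locus in enumerate(loci):
        data = build_locus_data(studies, locus, ld_by_ancestry_locus(locus))
        lead = int(
            np.flatnonzero(
                (data.variants["pos"] == locus.lead_pos)
                & (data.variants["effect_allele"] == locus.lead_effect_allele)
            )[0]
        )
        sset = dissect_locus(data, lead, p_locuswide=p_locuswide, lambda_gc=lam)
        sset = index_variants(data, sset, lambda_gc=lam)
        analyses.append(LocusAnalysis(locus, data, sset, lead))

        z_tracks = annotate_variants(data.variants, tracks)
        k_per_variant = np.sum(np.isfinite(data.z), axis=0)
        for signal in sset.signals:
            ok = signal.valid & (k_per_variant >= 1)
            if ok.sum() < 2:
                continue
            la = enr.ln_abf(signal.z_cond[ok], np.maximum(k_per_variant[ok], 1))
            abf = enr.signal_log_odds(la, signal_id=f"locus{li}_{signal.signal_id}")
            signal_abfs.append(abf)
            z_by_signal.append(z_tracks[ok])
            signal_pos.append(data.variants["pos"].to_numpy()[ok])

    names = [t.name for t in tracks]
    cats = {t.name: t.category for t in tracks}
    if signal_abfs and names:
        if forward_selection:
            selected: list[str] = []
            for cat in AnnotationTrack.CATEGORIES:
                in_cat = [n for n in names if cats[n] == cat]
                if in_cat:
                    selected += enr.forward_select(
                        signal_abfs, z_by_signal, names, in_cat, categories=cats
                    )
        else:
            selected = names
        model = enr.joint_model(signal_abfs, z_by_signal, names, selected, categories=cats)
    else:
        model = enr.joint_model(signal_abfs, z_by_signal, names, [], categories=cats)

    sel_cols = [names.index(a) for a in model.annotations]
    results = [
        fm.finemap_signal(
            abf.ln_abf,
            z[:, sel_cols],
            model,
            mass=mass,
            positions=pos,
            signal_id=abf.signal_id,
        )
        for abf, z, pos in zip(signal_abfs, z_by_signal, signal_pos)
    ]
    return PanelAnalysis(meta, log, analyses, signal_abfs, z_by_signal, model, results)
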