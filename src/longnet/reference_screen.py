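"""Reference dataset: the published worm RNAi screen of longevity-network
candidates.

These are the printed tallies and per-gene effect sizes of a
post-developmental RNAi lifespan screen of 374 essential candidate genes
drawn from worm and human longevity networks, kept here the way classic
packages ship canonical example datasets.  :func:`reference_statistics`
feeds them through the screen-analysis operations to recompute every
summary statistic of that screen — verification frequencies, the
extrapolation to untested preliminary hits, per-class detection rates,
fold-improvement over genome-wide baselines, and the effect-size summary.
"""

from __future__ import annotations

from .screen import (
    EffectMeasure,
    ScreenSummary,
    extrapolate_verified,
    fold_improvement,
    primary_detection_rates,
    round_half_up,
    summarize_effects,
    verification_frequency,
)

# --- network bookkeeping ---------------------------------------------------
LAGS_TOTAL = 555                 # curated worm longevity-associated genes
LAGS_IN_INTERACTOME = 218        # of which present in the PPI interactome
WLN_CORE = 205                   # retained in the worm longevity network
WLN_PARTNERS = 666               # their first-order partners
WLN_TOTAL = 871
HUMAN_CORE = 662                 # human core incl. model-organism orthologs

# --- candidate funnel ------------------------------------------------------
CANDIDATES_WLN = 228             # essential first-order partners, worm network
CANDIDATES_HLN = 272             # worm orthologs of human-network partners
CANDIDATES_OVERLAP = 54
CANDIDATES_TOTAL = 500
CLONES_WLN = 190                 # RNAi clone available, worm-network source
CLONES_HLN = 227
CLONES_SHARED = 43
CLONES_TOTAL = CLONES_WLN + CLONES_HLN - CLONES_SHARED   # 374 screened

# --- screening funnel per candidate class ----------------------------------
# (screened, prelim long, prelim short, retested long, retested short,
#  verified long, verified short)
WLN_SUMMARY = ScreenSummary(147, 47, 21, 24, 5, 10, 5)
HLN_SUMMARY = ScreenSummary(184, 45, 27, 17, 6, 7, 6)
SHARED_SUMMARY = ScreenSummary(43, 9, 7, 4, 1, 2, 0)
TOTAL_SUMMARY = ScreenSummary(374, 101, 55, 45, 12, 19, 11)

# Earlier screens used as baselines: (genes screened, verified long-lived).
GENOME_WIDE_BASELINES = ((16475, 89), (13300, 29))
ESSENTIAL_GENE_SCREEN = (2700, 64)

# --- longitudinally verified effect sizes (percent vs control) --------------
# Worm-network table; sequence name, %d mean lifespan, %d max (last-quartile).
WLN_EFFECTS = (
    EffectMeasure("T23D8.3", 25.7, 34.7),
    EffectMeasure("F37C12.9", 16.6, 21.7),     # rps-14
    EffectMeasure("T09A5.10", 16.4, 8.7),      # lin-5
    EffectMeasure("C03C10.3", 14.2, 21.7),     # rnr-2, shared with HLN
    EffectMeasure("F54E7.2", 11.6, 21.7),      # rps-12
    EffectMeasure("F09F7.3", 8.1, 21.7),
    EffectMeasure("C38D4.3", 6.5, 8.7),        # mel-28
    EffectMeasure("T20B12.8", 6.5, 0.0),       # hmg-4
    EffectMeasure("F35G12.10", 6.4, 0.0),      # asb-1
    EffectMeasure("F26F4.11", 6.4, 0.0),       # rpb-8, shared with HLN
    EffectMeasure("C47D12.2", 5.5, 8.7),
    EffectMeasure("K10B3.7", 5.3, 0.0),        # gpd-3
    EffectMeasure("R144.2", -18.9, -25.0),
    EffectMeasure("K07D4.3", -19.3, -25.0),    # rpn-11
    EffectMeasure("B0285.1", -22.2, -25.0),
    EffectMeasure("R13G10.1", -23.5, -25.0),   # dpy-27
    EffectMeasure("W07B3.2", -27.0, -38.0),    # gei-4
)
# Human-network table.
HLN_EFFECTS = (
    EffectMeasure("C03C10.3", 14.2, 21.7),     # rnr-2, shared with WLN
    EffectMeasure("R02D3.3", 13.0, 21.7),
    EffectMeasure("F10B5.6", 10.5, 8.7),       # emb-27
    EffectMeasure("F29G9.3", 7.9, 0.0),        # aps-1
    EffectMeasure("T09B4.10", 7.1, 8.7),       # chn-1
    EffectMeasure("F26F4.11", 6.4, 0.0),       # rpb-8, shared with WLN
    EffectMeasure("F28D9.1", 6.1, 0.0),        # rsr-1
    EffectMeasure("F18A1.5", 5.1, 21.7),       # rpa-1
    EffectMeasure("C01H6.5", 4.9, 8.7),        # nhr-23
    EffectMeasure("Y40B1A.4", -22.9, -37.0),   # sptf-3
    EffectMeasure("ZK1058.2", -28.1, -50.0),   # pat-3
    EffectMeasure("C52E4.4", -28.4, -50.0),    # rpt-1
    EffectMeasure("F26H9.6", -38.0, -50.0),    # rab-5
    EffectMeasure("D1014.3", -39.9, -50.0),    # snap-1
    EffectMeasure("K02D10.5", -48.6, -72.0),
)

# Sequence-name <-> common-name pairs from the verified tables, handy as an
# alias-map example for the loaders.
COMMON_NAME_ALIASES = {
    "rps-14": "F37C12.9", "lin-5": "T09A5.10", "rnr-2": "C03C10.3",
    "rps-12": "F54E7.2", "mel-28": "C38D4.3", "hmg-4": "T20B12.8",
    "asb-1": "F35G12.10", "rpb-8": "F26F4.11", "gpd-3": "K10B3.7",
    "rpn-11": "K07D4.3", "dpy-27": "R13G10.1", "gei-4": "W07B3.2",
    "emb-27": "F10B5.6", "aps-1": "F29G9.3", "chn-1": "T09B4.10",
    "rsr-1": "F28D9.1", "rpa-1": "F18A1.5", "nhr-23": "C01H6.5",
    "sptf-3": "Y40B1A.4", "pat-3": "ZK1058.2", "rpt-1": "C52E4.4",
    "rab-5": "F26H9.6", "snap-1": "D1014.3",
}


def reference_statistics() -> dict:
    """Recompute the reference screen's summary statistics from its tallies."""
    total = TOTAL_SUMMARY
    freq_long = verification_frequency(total, "long")
    freq_short = verification_frequency(total, "short")
    freq_long_raw = 100.0 * total.verified_long / total.genes_screened
    baselines = [100.0 * v / n for n, v in GENOME_WIDE_BASELINES]
    fold_int, fold_raw = fold_improvement(freq_long_raw, baselines)
    ext_long = extrapolate_verified(
        total.preliminary_long, total.retested_long, total.verified_long,
        total.genes_screened,
    )
    ext_short = extrapolate_verified(
        total.preliminary_short, total.retested_short, total.verified_short,
        total.genes_screened,
    )
    rates = {
        name: primary_detection_rates(
            s.genes_screened, s.preliminary_long, s.preliminary_short
        )
        for name, s in (
            ("wln", WLN_SUMMARY), ("hln", HLN_SUMMARY), ("shared", SHARED_SUMMARY)
        )
    }
    n_long, mean_long, n_modest = summarize_effects(
        WLN_EFFECTS + HLN_EFFECTS, "long", modest_cutoff=10.0
    )
    n_short, mean_short, _ = summarize_effects(
        WLN_EFFECTS + HLN_EFFECTS, "short", modest_cutoff=10.0
    )
    return {
        "verified_long_pct": freq_long,
        "verified_short_pct": freq_short,
        "verified_long_pct_raw": round_half_up(freq_long_raw, 2),
        "baseline_mean_pct": round_half_up(sum(baselines) / len(baselines), 2),
        "fold_improvement": fold_int,
        "fold_improvement_raw": round_half_up(fold_raw, 2),
        "extrapolated_long": ext_long[0],
        "extrapolated_long_pct": ext_long[1],
        "extrapolated_short": ext_short[0],
        "extrapolated_short_pct": ext_short[1],
        "detection_rates": rates,
        "n_verified_long_effects": n_long,
        "mean_long_effect_pct": mean_long,
        "n_modest_long_effects": n_modest,
        "n_verified_short_effects": n_short,
        "mean_short_effect_pct": mean_short,
        "coverage_pct": round_half_up(100.0 * WLN_CORE / LAGS_IN_INTERACTOME, 1),
        "screened_total": CLONES_TOTAL,
    }
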