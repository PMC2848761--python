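"""Published reference tables from the soybean LoPro/HiPro NIL seed-fill study.

These small tables are shipped with the package so that the screening rules
(fold-change and significance thresholds) and the region logic can be
exercised and audited against published numbers without any external data.
All tables are returned as fresh pandas DataFrames.

Notation: LoPro is the recurrent low-protein/high-oil *G. max* line, HiPro
the introgressed high-protein *G. soja* NIL; A1–A4 are LoPro read libraries
at seed-fill stages 1–4 and B1–B4 the HiPro equivalents.
"""

from __future__ import annotations

import io

import pandas as pd

#: Non-segregating SSR markers flanking the seed-protein QTL introgression
#: on chromosome 20 (LG I), bp positions from the published physical map.
QTL_BORDER_MARKERS = {
    "Sat_174": ("Gm20", 24_540_000),
    "ssrpqtl_38": ("Gm20", 32_920_000),
}

_GENOTYPE_CONTRAST_TSV = """\
probeset\tlopro_mean\thipro_mean\tratio\tp\tfdr\tchromosome\tstart\tstop
Gma.7719.1.A1_at\t7705\t401\t19.22\t2.43e-15\t9.16e-11\t20\t26511887\t26511422
GmaAffx.74372.1.S1_at\t2478\t502\t4.94\t2.63e-12\t1.98e-08\t20\t26512404\t26511978
Gma.1680.1.S1_x_at\t289926\t63810\t4.54\t5.51e-15\t1.04e-10\t20\t32331958\t32332062
Gma.1680.1.S1_at\t134237\t30039\t4.47\t1.05e-14\t1.32e-10\t20\t32331999\t32332062
GmaAffx.49130.1.S1_at\t10163\t842\t12.06\t4.38e-13\t4.12e-09\t20\t30182754\t30182479
GmaAffx.67113.1.S1_at\t8643\t1438\t6.01\t2.19e-10\t9.17e-07\t20\t30182353\t30181939
GmaAffx.65278.1.A1_at\t2695\t5039\t0.53\t5.95e-12\t3.74e-08\t20\t31053180\t31054158
Gma.926.1.A1_at\t2047\t1031\t1.99\t2.99e-11\t1.61e-07\t20\t31812657\t31812894
GmaAffx.55722.1.S1_at\t12024\t5126\t2.35\t1.01e-10\t4.74e-07\t20\t26515177\t26514175
GmaAffx.69807.1.A1_at\t8369\t13209\t0.63\t8.08e-07\t2.42e-03\t17\t1020953\t1020579
Gma.10034.1.A1_at\t1563\t2548\t0.61\t8.35e-07\t2.42e-03\t18\t13340405\t13340201
GmaAffx.42487.1.S1_at\t9513\t5786\t1.64\t1.51e-06\t3.79e-03\t18\t12183748\t12183617
GmaAffx.47978.1.S1_at\t3007\t1378\t2.18\t2.31e-05\t4.58e-02\t7\t897321\t897126
"""

_HIPRO_STAGE_TSV = """\
probeset\tp\tstage1_mean\tstage4_mean\tratio
Gma.1017.1.S1_at\t1.57e-09\t750\t815093\t1086.8
Gma.1017.1.S1_s_at\t4.06e-06\t2032\t952032\t468.5
Gma.1017.2.S1_a_at\t7.97e-06\t5017\t1160437\t231.3
Gma.8531.1.S1_at\t2.67e-05\t3496\t711843\t203.6
Gma.11119.2.S1_s_at\t9.84e-05\t1209\t139593\t115.4
GmaAffx.48565.1.S1_at\t8.72e-05\t4270\t421867\t98.8
AFFX-Gm_SucBP_5_at\t3.42e-07\t3406\t332671\t97.7
Gma.10058.1.S1_at\t5.23e-05\t6724\t510079\t75.9
Gma.939.1.A1_at\t1.31e-04\t13550\t833645\t61.5
Gma.2505.1.S1_a_at\t3.11e-05\t2463\t112324\t45.6
Gma.10.1.S1_at\t5.93e-04\t3516\t141501\t40.2
Gma.2505.1.S1_at\t7.47e-05\t5640\t215422\t38.2
GmaAffx.8078.1.S1_at\t1.38e-04\t7347\t277493\t37.8
GmaAffx.24413.1.A1_at\t1.01e-04\t3559\t117894\t33.1
Gma.8445.1.S1_at\t5.03e-04\t1066\t34010\t31.9
"""

_LOPRO_STAGE_TSV = """\
probeset\tp\tstage1_mean\tstage4_mean\tratio
GmaAffx.35952.1.S1_at\t6.07e-05\t3847\t573557\t149.1
Gma.4624.1.S1_s_at\t2.83e-06\t782\t17143\t21.9
GmaAffx.22552.1.S1_at\t2.58e-04\t2487\t40880\t16.4
Gma.17917.1.S1_at\t6.95e-05\t707\t7033\t9.9
Gma8516.1.S1_at\t1.33e-05\t3512\t32139\t9.2
soybean_rRNA_114_RC_at\t4.66e-04\t13887\t121092\t8.7
GmaAffx.90956.1.S1_s_at\t3.74e-05\t22279\t186953\t8.4
GmaAffx.71277.1.S1_at\t1.46e-04\t2085\t15568\t7.5
GmaAffx.39349.1.S1_at\t2.26e-04\t23625\t166676\t7.1
GmaAffx.34293.1.S1_at\t3.92e-04\t522\t3482\t6.7
GmaAffx.87730.1.S1_at\t9.35e-04\t7132\t45243\t6.3
GmaAffx.75384.1.S1_at\t2.26e-04\t5443\t33676\t6.2
Gma.8612.1.S1_at\t7.46e-04\t3282\t19869\t6.1
Gma.12309.1.S1_at\t6.90e-05\t38247\t228429\t6.0
Gma.6617.1.S1_at\t8.37e-05\t2823\t16373\t5.8
"""

_HTTS_DE_TSV = """\
comparison\tgene\tcount_a\tcount_b\tchromosome\tstart\tend\tstrand
Overall\tGlyma20g18880\t51\t0\tGm20\t26510968\t26513359\t-
Stage 3\tGlyma20g18880\t15\t0\tGm20\t26510968\t26513359\t-
Stage 4\tGlyma20g18880\t18\t0\tGm20\t26510968\t26513359\t-
Stage 4\tGlyma20g19620\t268\t106\tGm20\t27706435\t27707431\t+
Stage 4\tGlyma20g19630\t259\t95\tGm20\t27706477\t27706935\t-
Overall\tGlyma20g19680\t24\t2\tGm20\t27899125\t27899596\t-
Stage 3\tGlyma20g19680\t24\t0\tGm20\t27899125\t27899596\t-
Overall\tGlyma20g21030\t61\t12\tGm20\t29984895\t29986397\t+
Stage 1\tGlyma20g21030\t36\t4\tGm20\t29984895\t29986397\t+
Overall\tGlyma20g21040\t40\t8\tGm20\t29984951\t29986210\t-
Stage 1\tGlyma20g21040\t27\t4\tGm20\t29984951\t29986210\t-
Overall\tGlyma20g21080\t13\t0\tGm20\t30044891\t30045091\t+
Overall\tGlyma20g21140\t76\t0\tGm20\t30178277\t30182887\t-
Stage 1\tGlyma20g21140\t13\t0\tGm20\t30178277\t30182887\t-
Stage 3\tGlyma20g21140\t38\t0\tGm20\t30178277\t30182887\t-
Stage 4\tGlyma20g21140\t15\t0\tGm20\t30178277\t30182887\t-
Overall\tGlyma20g21540\t32\t0\tGm20\t30873568\t30873806\t+
Stage 3\tGlyma20g21540\t13\t0\tGm20\t30873568\t30873806\t+
Stage 3\tGlyma20g21780\t121\t36\tGm20\t31386550\t31389333\t+
Stage 3\tGlyma20g22170\t142\t46\tGm20\t32098751\t32103750\t+
Stage 1\tGlyma20g22650\t9\t42\tGm20\t32589230\t32589715\t+
"""

_TOP_EXPRESSED_TSV = """\
gene\tstrand\tstart\tstop\tA1\tA2\tA3\tA4\tB1\tB2\tB3\tB4\ttotal
Glyma20g19510.1\t+\t27301033\t27301656\t1301\t575\t810\t535\t1335\t1012\t404\t296\t6268
Glyma20g21190.1\t+\t30239601\t30241733\t290\t210\t339\t212\t407\t175\t225\t190\t2048
Glyma20g22430.1\t+\t32447769\t32449767\t240\t136\t201\t194\t385\t227\t156\t156\t1695
Glyma20g22680.1\t+\t32606778\t32610170\t245\t187\t274\t146\t347\t133\t132\t114\t1578
Glyma20g21230.1\t-\t30345305\t30346033\t305\t118\t234\t48\t509\t185\t111\t52\t1562
Glyma20g22090.1\t+\t31989263\t31993579\t222\t147\t243\t142\t304\t133\t241\t112\t1544
Glyma20g21970.1\t-\t31790681\t31793219\t140\t130\t165\t121\t297\t160\t229\t181\t1423
Glyma20g22600.1\t+\t32546273\t32550838\t224\t121\t247\t171\t213\t103\t131\t127\t1337
Glyma20g17960.1\t-\t25068695\t25074232\t205\t103\t236\t106\t190\t136\t158\t122\t1256
Glyma20g20010.1\t+\t28403441\t28407180\t254\t103\t148\t109\t266\t124\t130\t92\t1226
"""


def _read(tsv: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(tsv), sep="\t")


def genotype_contrast_table() -> pd.DataFrame:
    """The 13 probesets differentially accumulated between LoPro and HiPro.

    Columns: probeset, linear means per genotype, LoPro/HiPro mean ratio,
    t-test p, BH FDR, and mapped genome coordinates (start/stop as printed,
    which may be reversed for minus-orientation alignments).
    """
    return _read(_GENOTYPE_CONTRAST_TSV)


def hipro_stage_table() -> pd.DataFrame:
    """Top 15 probesets up-regulated stage 4 vs stage 1 within HiPro."""
    return _read(_HIPRO_STAGE_TSV)


def lopro_stage_table() -> pd.DataFrame:
    """Top 15 probesets up-regulated stage 4 vs stage 1 within LoPro."""
    return _read(_LOPRO_STAGE_TSV)


def htts_de_table() -> pd.DataFrame:
    """Read-count DE comparisons in the QTL region (12 distinct genes).

    ``count_a``/``count_b`` are the published per-comparison count pairs
    (LoPro then HiPro).  One gene's published coordinates were internally
    inconsistent between rows; the consistent per-stage coordinates are used.
    """
    return _read(_HTTS_DE_TSV)


def top_expressed_table() -> pd.DataFrame:
    """Ten most highly expressed genes in the QTL region with per-library counts."""
    return _read(_TOP_EXPRESSED_TSV)
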