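# Synthetic stand-in WNT-target panel: canonical WNT/beta-catenin target
# gene symbols with invented probe identifiers (editable).
gene_symbol	probe_id
AXIN2	200001_at
AXIN2	200002_s_at
CCND1	200003_at
CCND1	200004_s_at
MYC	200005_at
MYC	200006_s_at
CD44	200007_at
CD44	200008_s_at
GREM2	200009_at
LGR5	200010_at
ASCL2	200011_at
SOX9	200012_at
JUN	200013_at
FOSL1	200014_at
MMP7	200015_at
MMP7	200016_s_at
BMP4	200017_at
DKK1	200018_at
NKD1	200019_at
TCF7	200020_at
ID2	200021_at
BIRC5	200022_at
VEGFA	200023_at
VEGFA	200024_s_at
CLDN1	200025_at
EDN1	200026_at
EGFR	200027_at
EGFR	200028_s_at
FGF9	200029_at
FST	200030_at
FZD7	200031_at
IGF2	200032_at
IL6	200033_at
JAG1	200034_at
MET	200035_at
MET	200036_s_at
CDH1	200037_at
CDKN2A	200038_at
PTGS2	200039_at
MMP2	200040_at
MMP9	200041_at
NRCAM	200042_at
PPARD	200043_at
RUNX2	200044_at
SNAI1	200045_at
SOX17	200046_at
TIAM1	200047_at
TNFRSF19	200048_at
TWIST1	200049_at
WISP1	200050_at
WISP2	200051_at
GJA1	200052_at
EPHB2	200053_at
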