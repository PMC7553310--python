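"""Select upregulated genes and classify them as early/intermediate/late.

Generates the default class-structured expression matrix (21 early, 27
intermediate, 5 late genes; log2 scale, paired treated/untreated
triplicates), selects significantly upregulated genes (paired t-test
p < 0.05, fold change > 2) and classifies them by their time of maximal
induction: early t_max <= 4 h, intermediate t_max = 8 h, late t_max >= 12 h.
"""

from isgdyn.classify import classify_by_tmax, order_for_heatmap, select_upregulated
from isgdyn.synth import GeneratorConfig, generate_expression_matrix

matrix, truth = generate_expression_matrix(cfg=GeneratorConfig(seed=0))

selected = select_upregulated(matrix, alpha=0.05, min_fold=2.0)
print(f"significantly upregulated: {len(selected)} of {len(matrix.genes)} genes")

table = classify_by_tmax(matrix.induction())
print("\nclass counts (truth in parentheses):")
for cls in ("early", "intermediate", "late"):
    n = (table["class"] == cls).sum()
    n_true = (truth["class"] == cls).sum()
    print(f"  {cls:>12s}: {n:2d} ({n_true})")

accuracy = (table["class"] == truth["class"]).mean()
print(f"\nagreement with generating classes: {accuracy:.1%}")

order = order_for_heatmap(table, matrix)
print("first five genes in heatmap order (t_max asc, 1 h fold change desc):",
      ", ".join(order[:5]))
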