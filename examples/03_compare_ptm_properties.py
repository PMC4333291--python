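"""Do phosphoproteins sit in more connected network positions?

Plants a degree bias (carriage probability ~ (k+1)^1) for phosphorylation
and none for acetylation, then compares each carrier set against the rest
of the network with a two-sided Mann-Whitney test and log2 median fold
changes, BH-FDR adjusted per property.
"""

from ptmnet import compare, pin, synthetic
from ptmnet.synthetic import PTMTypeSpec, SimulationConfig

cfg = SimulationConfig(
    seed=9, n_proteins=2000,
    ptm_types=[PTMTypeSpec("phosphorylation", alpha=0.15, beta=1.0),
               PTMTypeSpec("acetylation", alpha=0.15, beta=0.0)],
)
net = synthetic.generate_network(cfg)
carriers = synthetic.carrier_sets(net, cfg)
props = pin.property_table(net)

results = []
for t, s in sorted(carriers.items()):
    results.extend(compare.compare_type(props, s, ptm_type=t))
compare.adjust_results(results)

for r in results:
    print(f"{r.ptm_type:>16} {r.property:>10}: log2 fold {r.log2_fold:+.3f} "
          f"({r.fold_basis}), FDR p {r.p_fdr:.2e}, direction {r.direction}")
# Expect: phosphorylation strongly 'higher' on degree (the planted bias),
# acetylation near zero fold with non-significant p.
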