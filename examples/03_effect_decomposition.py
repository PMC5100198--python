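"""Decompose effects in a fitted path diagram into direct/indirect/total.

Uses the published blood-pressure fragment: the gene MET affects systolic
blood pressure (SBP) directly and through diastolic blood pressure (DBP).
"""

from sparsesem import decompose, effect_table, network_from_edges

G = network_from_edges([
    ("MET", "SBP", -0.0596),   # direct path coefficient
    ("MET", "DBP", 0.0621),    # gene -> mediator
    ("DBP", "SBP", 0.605),     # mediator -> outcome
])

rec = decompose(G, "MET", "SBP")
print(f"direct   {rec.direct:+.4f}")
print(f"indirect {rec.indirect:+.4f}   (= 0.0621 x 0.605)")
print(f"total    {rec.total:+.4f}")
# The total effect is the sum over all directed paths of the product of
# path coefficients: the mediated pathway almost cancels the direct one,
# so intervening on MET changes SBP far less than the direct edge alone
# suggests.

table, flagged = effect_table(G)
print("\nfull effect table:")
print(table.to_string(index=False))
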