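"""Score predicted network topologies with precision and recall.

Directed edges are compared exactly against the known truth: recall is the
fraction of true connections captured, precision the fraction of predicted
connections that are real.  The two worked examples below mirror the
characteristic outcomes of noisy network identification: extra false
edges lower precision only; missed true edges lower recall only.
"""

from ssgrn import benchmark_5gene, edges_of, precision_recall

truth = edges_of(benchmark_5gene())  # 7 directed edges
print(f"true network: {len(truth)} edges")

# all 7 true edges found plus 2 spurious ones
pred = set(truth) | {(1, 2), (1, 3)}
m = precision_recall(pred, truth)
print(f"\n7 true + 2 spurious: recall = {m.recall:.2f}, precision = {m.precision:.2f}")
print("  (every real connection captured, but 2 of 9 predictions are wrong)")

# only 4 of the 7 true edges found, nothing spurious
pred = {(0, 2), (1, 0), (3, 2), (4, 3)}
m = precision_recall(pred, truth)
print(f"\n4 of 7 true, 0 spurious: recall = {m.recall:.2f}, precision = {m.precision:.2f}")
print("  (a conservative prediction: everything found is real, much is missed)")
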