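"""Consensus-superiority benchmark on synthetic two-source data.

Generates mutations whose true ddG has one component visible only to the
distance-signature branch and one only to the substitution branch, trains
the full pipeline, and compares held-out correlations on a position-level
blind split.
"""
import tempfile

from protstab import consensus_benchmark

with tempfile.TemporaryDirectory() as workdir:
    result = consensus_benchmark(seed=1, out_dir=workdir, n=400)

print(f"train mutations: {result['n_train']}, blind-test mutations: {result['n_test']}")
print(f"held-out Pearson r, signature component alone : {result['r_mcsm']:.3f}")
print(f"held-out Pearson r, calibrated substitution   : {result['r_sdm']:.3f}")
print(f"held-out Pearson r, consensus                 : {result['r_consensus']:.3f}")
print(f"residual standard error (consensus)           : {result['sigma_consensus']:.3f} kcal/mol")
print(f"after 10% outlier removal                     : r {result['r_consensus_90']:.3f}, "
      f"sigma {result['sigma_consensus_90']:.3f}")
print("\nEach component sees only one of the two signal sources, so neither can")
print("explain the data alone; the consensus, fed both predictions, recovers")
print("substantially more of the held-out variance than either component.")
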