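"""Iterative consensus contact map of a decoy ensemble.

The consensus keeps the contacts present in at least 25% of an iteratively
refined 25% subset of the ensemble: starting from all decoys, threshold
the contact-frequency matrix M at mu = 0.25, re-select the quarter of the
ensemble closest to that map in Hamming distance, and repeat until stable.
"""

from funnelpot import SynthConfig, consensus_contact_map, contact_map, \
    gen_decoys, gen_native

cfg = SynthConfig(n_res=30, n_decoys=40, noise_grid=[1.0, 2.0, 6.0], seed=4)
native = gen_native(cfg)
ensemble = gen_decoys(native, cfg)

state = consensus_contact_map(ensemble, mu=0.25, keep=0.25)
native_map = contact_map(native)

shared = (state.S.contacts & native_map.contacts).sum() // 2
print(f"native contacts (9 A, |i-j| >= 3): {native_map.count()}")
print(f"consensus contacts:                {state.S.count()}")
print(f"shared with native:                {shared}")
print(f"converged after {state.iteration} iteration(s); "
      f"{len(state.selected)} decoys selected")
print("\nLow-noise decoys dominate the refined subset, so the consensus "
      "recovers most native contacts without ever seeing the native.")
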