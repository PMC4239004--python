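"""Compute the four native-decoy distance measures on a synthetic ensemble.

Builds a compact 30-residue chain, perturbs it at two noise levels, and
prints RMSD (Å), GDT-TS* and Q* (both in [0, 1]) and MT (elastic energy)
for each decoy.  Extrinsic measures (RMSD, GDT-TS*) compare superposed
coordinates; intrinsic ones (Q*, MT) compare internal distances only, so
they ignore the random rigid motion applied to every decoy.
"""

from funnelpot import SynthConfig, gen_decoys, gen_native, measure

cfg = SynthConfig(n_res=30, n_decoys=6, noise_grid=[1.0, 4.0], seed=11)
native = gen_native(cfg)
ensemble = gen_decoys(native, cfg)

print(f"native: {ensemble.n_res} residues, seq {native.seq[:20]}...")
print(f"{'decoy':<22}{'RMSD':>8}{'GDT-TS*':>9}{'Q*':>7}{'MT':>9}")
for decoy in ensemble.decoys:
    vals = [measure(native, decoy, w)
            for w in ("rmsd", "gdt", "q", "mt")]
    print(f"{decoy.id:<22}{vals[0]:8.2f}{vals[1]:9.3f}"
          f"{vals[2]:7.3f}{vals[3]:9.2f}")

print("\nLarger noise raises every measure: sigma=1 decoys stay "
      "near-native, sigma=4 decoys lose up to half their native contacts.")
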