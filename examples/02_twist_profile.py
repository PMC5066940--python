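"""Measure helical twist along an ideal duplex with a locally unwound step.

Builds a duplex at uniform 36-degree twist except step 3 (20 degrees), then
recovers the profile from base-pair reference frames -- the machine twin of
a per-step twist plot.
"""

from duplexlens import (GeneratorSpec, build_helix, complement_sequence,
                        pair_duplex, twist_profile)

spec = GeneratorSpec(sequence="CGCGAATTCGCG", twist_overrides={3: 20.0})
duplex, truth = build_helix(spec)
dmap = pair_duplex(duplex, spec.sequence, complement_sequence(spec.sequence))

print("step  twist(deg)  rise(A)   built-as")
for sp, t in zip(twist_profile(duplex, dmap), truth):
    print(f"{sp.step:4d}  {sp.twist:9.2f}  {sp.rise:7.3f}   {t['twist']:.1f}")

# The analyzer recovers the generator's ground truth to ~0.01 degree; the
# dip at step 3 is the signature of local unwinding.
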