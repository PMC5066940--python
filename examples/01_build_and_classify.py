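"""Build a lesion-bearing duplex and classify its backbone substates.

Generates the Drew-Dickerson dodecamer with 8-oxoguanine at position 4 and
BII torsions (epsilon 270, zeta 180) injected at the step 3' of the lesion,
then reports the per-step epsilon-zeta difference and BI/BII call.
"""

from duplexlens import (GeneratorSpec, backbone_torsions, build_torsion_exact,
                        classify_step)

spec = GeneratorSpec(sequence="CGCXAATTCGCG", eps_zeta={4: (270.0, 180.0)})
duplex = build_torsion_exact(spec)

print("step  eps     zeta    eps-zeta  state")
for residue in duplex.chain("A")[:-1]:
    call = classify_step(backbone_torsions(duplex, 0, "A", residue.index))
    print(f"{call.step:4d}  {call.epsilon:6.1f}  {call.zeta:6.1f}  "
          f"{call.eps_minus_zeta:+8.1f}  {call.state}")

# A BII step has eps-zeta above +20 degrees; the injected lesion step 4
# stands out against the all-BI background (around -40 here).
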