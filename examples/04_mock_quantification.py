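"""Quantify SDP composition from barcoded mock amplicon reads.

Simulates a 24-sample mock panel (members at 0.02%-50%), pools barcoded
reads, then demultiplexes, dereplicates, classifies at 97% identity and
tabulates RA_SDP = NR_SDP / NR_assigned x 100.  Prints the estimated vs true
composition of three samples and the log-scale R^2 over the whole panel.
"""

import math

import numpy as np

import sdpmark as sm

seed, depth = 42, 20_000
aln, part, _ = sm.simulate_gene_family(sm.SimSpec(seed=seed))
amps = sm.representative_amplicons(aln, part)
design = sm.default_mock_design(part.sdps)
sheet = sm.make_sample_sheet(design, seed=seed)
batch, _ = sm.simulate_mock_reads(amps, sheet, depth=depth, seed=seed)

by_sample, unassigned = sm.demultiplex(batch, sheet)
features = sm.dereplicate(by_sample)
refs = [sm.GeneRecord(f"{s}_rep", q, sdp=s) for s, q in amps.items()]
table = sm.abundance(features, sm.classify(features, refs))

print(f"{len(batch)} reads, {unassigned} unassigned, "
      f"{len(features.feature_ids)} unique features\n")
for s in sheet[:3]:
    print(f"{s.sample_id}: true -> estimated RA (%)")
    for sdp, frac in sorted(s.known_composition.items()):
        est = table.relative.at[s.sample_id, sdp]
        print(f"  {sdp}: {frac * 100:8.3f} -> {est:8.3f}")

xs, ys = [], []
for s in sheet:
    for sdp, frac in s.known_composition.items():
        est = table.relative.at[s.sample_id, sdp]
        if frac > 0 and est > 0:
            xs.append(math.log10(frac * 100))
            ys.append(math.log10(est))
r2 = np.corrcoef(xs, ys)[0, 1] ** 2
print(f"\nlog-scale R^2 over {len(xs)} detected (sample, member) points: {r2:.4f}")
# Error-free reads and exact classification leave only multinomial sampling
# noise, so the panel-wide R^2 sits essentially at 1.
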