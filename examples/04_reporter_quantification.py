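"""Quantify reporter-assay and immunoblot readouts.

The relative response ratio (RRR) expresses a luciferase signal in percent
between its negative (0%) and positive (100%) controls; per-well renilla
normalization removes transfection-efficiency differences; the phospho-blot
ratio normalizes phospho-protein to total protein and a loading control.
"""

from sh2fp import (BlotMeasurement, ReporterMeasurement,
                   normalized_phospho_ratio, relative_response_ratio,
                   replicate_stats, reporter_normalize)

wells = [(5000, 1000, 5000), (3000, 1000, 5000), (1800, 1000, 5000)]
for sample, neg, pos in wells:
    rrr = relative_response_ratio(ReporterMeasurement(sample, neg, pos))
    print(f"sample {sample:5d} AU -> relative response {rrr:6.1f} %")

triplicate = [reporter_normalize(f, r) for f, r in ((10.2, 2.0), (11.8, 2.4),
                                                    (9.6, 1.9))]
mean, sd = replicate_stats(triplicate)
print(f"\nrenilla-normalized activity: mean {mean:.2f}, SD {sd:.2f} (n=3)")

blot = BlotMeasurement(phospho=2.0, total=4.0, loading=1.0)
print(f"normalized phospho ratio (2, 4, 1): {normalized_phospho_ratio(blot)}")
# 100% means the sample activated the reporter as strongly as the positive
# control; the blot ratio is dimensionless and comparable across lanes.
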