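"""End-to-end recovery on a synthetic cohort with known ground truth.

Generates a 16-tumor cohort (germline null alleles under Hardy-Weinberg,
somatic chr-arm loss, qPCR plates with replicate noise), re-quantifies
copy numbers from the plate Ct values, classifies deletion-history
variants, and compares against the generator's ground truth.
"""

import io

from gstnull import (
    SimulationConfig,
    classify_variant,
    estimate_copy_number,
    fit_standard_curve,
    generate_cohort,
)
from gstnull.genotype import PairedLocusObservation
from gstnull.qpcr import read_dilution_series, read_plate

config = SimulationConfig(seed=11, ct_noise_sd=0.15, n_primary=12, n_recurrent=4)
bundle = generate_cohort(config)

curves = {}
for assay, frame in bundle.dilution_series.items():
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    curves[assay] = fit_standard_curve(read_dilution_series(buf))

buf = io.StringIO()
bundle.plates.to_csv(buf, sep="\t", index=False)
buf.seek(0)
wells = {(m.sample_id, m.assay): m for m in read_plate(buf)}

recovered = 0
for _, row in bundle.truth.iterrows():
    sid = row["sample_id"]
    copies = {
        gene: estimate_copy_number(
            wells[(sid, gene)], wells[(sid, "APOB")], curves[gene], curves["APOB"]
        ).integer_call
        for gene in ("GSTM1", "GSTM2")
    }
    call = classify_variant(PairedLocusObservation(sid, copies["GSTM1"], copies["GSTM2"]))
    truth = classify_variant(
        PairedLocusObservation(sid, int(row["poly_copies"]), int(row["neighbor_copies"]))
    )
    recovered += call.variant == truth.variant

print(f"seed {config.seed}: recovered {recovered}/{len(bundle.truth)} "
      f"deletion-history variants from noisy plates (Ct sd {config.ct_noise_sd})")
rec = bundle.truth[bundle.truth["group"] == "recurrent"]
print(f"recurrent tumors simulated as null genotype: "
      f"{(rec['poly_copies'] == 0).sum()}/{len(rec)}")
# with 3 replicates and realistic Ct noise, integer copy calls are almost
# always exact, so the variant labels match the generating configuration
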