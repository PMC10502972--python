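"""Compare automated (network + post-processing) SfChT measurements with
the ground-truth values, the phantom analogue of validating an automated
reader against a human grader: a linear regression of paired
measurements should give slope ~1, intercept ~0, Pearson R near 1.
"""

from choroidseg import (NetworkConfig, TrainConfig, build_network, clean_mask,
                        compare_manual_auto, generate_scan_set, measure_sfcht,
                        predict, train)
from choroidseg.pipeline import make_phantom_dataset

train_set = [(b, m) for b, m, _ in make_phantom_dataset(30, "tiny", seed=100)]
model = build_network(NetworkConfig.tiny(seed=1))
model, _ = train(model, train_set, TrainConfig(epochs=20, seed=1))

pairs = []
for i, (_, _, spec) in enumerate(make_phantom_dataset(10, "tiny", seed=300)):
    scans = generate_scan_set(spec, jitter_seed=i)
    auto = measure_sfcht(
        [(b, clean_mask(predict(model, b.pixels))) for b, _ in scans])
    manual = measure_sfcht([(b, m) for b, m in scans])
    pairs.append((manual.mean_um, auto.mean_um))
    print(f"phantom {i}: manual {manual.mean_um:7.2f} um   "
          f"auto {auto.mean_um:7.2f} um")

slope, intercept, r = compare_manual_auto(pairs)
print(f"\nauto = {slope:.3f} x manual + {intercept:.2f};  R = {r:.4f}")
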