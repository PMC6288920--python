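"""De-stripe an artifact-laden image and apply the QC gates.

Shows the two preprocessing roles: counting full-width white lines for
the discard rule (more than two lines, or signal-strength index below 40)
and suppressing the stripes with the bandpass + directional notch filter.
"""

import numpy as np

from octavd import (EnFaceImage, PhantomConfig, add_motion_artifacts,
                    count_white_lines, gaussian_bandpass,
                    generate_vessel_network, qc_evaluate)

image, _ = generate_vessel_network(PhantomConfig(seed=1))
corrupted = add_motion_artifacts(image, n_lines=3, seed=2)

lines = count_white_lines(corrupted)
enface = EnFaceImage(pixels=corrupted, scan_type="macula",
                     segment_label="superficial_retina", laterality="OD",
                     subject_id="DEMO", scan_index=1,
                     signal_strength_index=55.0)
report = qc_evaluate(enface, lines)
print(f"white lines detected: {lines}")
print(f"high motion (>2 lines): {report.high_motion}  -> discarded: {report.discarded}")

filtered = gaussian_bandpass(corrupted, stripe_notch=True)


def stripe_energy(img):
    spectrum = np.abs(np.fft.fft2(img - img.mean())) ** 2
    return spectrum[:, 0].sum() / spectrum.sum()  # share at zero horiz. freq.


print(f"stripe-band energy share before: {stripe_energy(corrupted):.3f}")
print(f"stripe-band energy share after:  {stripe_energy(filtered):.3f}")
# A segment with 3 lines is discarded; for retained images the notch
# removes nearly all horizontal-stripe energy before vessel detection.
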