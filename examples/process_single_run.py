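"""Pulse-level quality control of a single pulsed-nanospray acquisition.

Simulates one 40-pulse run (~0.8 Hz pulse train, 6-7 scans per pulse, 10%
pulse-to-pulse amplitude variability, 10% outlier pulses at 1.5x amplitude),
detects the pulses on the total ion chronogram, measures the spiked internal
standard's extracted-ion area in each pulse, rejects pulses outside the
+/-20%-of-median IS window, randomly selects five survivors, and averages
their scans into the run's representative spectrum.
"""

import numpy as np

from pulsedims import synth, pulses as pp

panel = synth.generate_panel(n_features=30, n_differential=0, fc=1.0, seed=5)
acq = synth.AcquisitionConfig()  # 40 pulses at 0.8 Hz, 0.1 s scans
run, truth = synth.generate_run(panel, panel.base_abundance, acq, seed=5)
print(f"simulated {len(run)} scans over {run[-1].scan_time:.0f} s "
      f"({truth.outlier_pulse.sum()} outlier pulses planted)")

tic = pp.compute_tic(run)
pulses = pp.detect_pulses(tic, min_height=0.05 * tic.intensities.max(), min_scans=3)
print(f"detected {len(pulses)} pulses, "
      f"mean {np.mean([p.scan_count for p in pulses]):.1f} scans/pulse")

eic = pp.extract_eic(run, panel.is_mz, tol_ppm=10.0)
areas = pp.integrate_over_pulses(eic, pulses)
kept, rejected = pp.reject_outlier_pulses(pulses, areas)
med = np.median(areas)
print(f"IS EIC area median {med:.0f}; QC window [{0.8 * med:.0f}, {1.2 * med:.0f}] "
      f"-> kept {len(kept)}, rejected {len(rejected)}")

selected = pp.select_pulses(kept, k=5, seed=7)
spec = pp.representative_spectrum(run, selected, mz_bin_ppm=10.0,
                                  instrument_threshold=2e3, sample_id="demo")
print(f"representative spectrum from {len(selected)} pulses: "
      f"{spec.mz.size} peaks above the 2e3-count abundance threshold")
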