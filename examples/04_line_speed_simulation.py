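"""Line-scan camera throughput and poultry line-speed feasibility.

Uses the two hypothetical camera presets (a 256k-pixel SWIR unit at 320×800
and a 108k-pixel NIR unit at 640×168, both 96 bands) to convert an inference
pixel rate into hypercubes per second and judge it against 140 and 250
birds-per-minute line speeds (two halved fillets per bird). The latency
protocol (5 warm-ups, 10 timed repetitions) is demonstrated on the real
scorer; wall-clock numbers are machine-dependent by nature.
"""

import numpy as np

import hsifm as h

model = h.build_discriminator(seed=0)
batch = np.random.default_rng(0).random((2604, 96)).astype(np.float32)  # ~1 MB

stats = h.measure_latency(lambda b: h.score_spectra(model, b), batch)
pixels_per_s = batch.shape[0] / stats.mean_s
print(f"latency over {stats.reps} reps (after {stats.warmup_runs} warm-ups): "
      f"{stats.mean_s * 1e3:.1f} ms -> {pixels_per_s:,.0f} px/s, "
      f"{h.throughput(batch.size * 4, stats.mean_s):.1f} MB/s")

for cam in (h.swir_camera(), h.nir_camera()):
    exact, whole = h.hypercube_rate(pixels_per_s, cam)
    geom = h.scan_geometry(228.6, 127.0, cam,
                           "perpendicular" if "swir" in cam.name else "parallel")
    print(f"\n{cam.name}: {h.hypercube_pixels(cam):,} spectra/cube, "
          f"fillet needs {geom.required_width_px}x{geom.required_lines} "
          f"({'fits' if geom.fits else 'does not fit'})")
    print(f"  inference rate: {exact:.2f} cubes/s (floor {whole}); "
          f"optics allow {h.acquisition_limit(cam):.2f} cubes/s")
    for bpm in (140, 250):
        v = h.feasibility(exact, bpm)
        print(f"  {bpm} BPM needs {v.required_per_s} fillets/s -> "
              f"{'feasible' if v.feasible else 'infeasible'} "
              f"(margin {v.margin:+.1f})")
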