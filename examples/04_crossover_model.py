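"""Fit the cost planes to the published timing samples and locate the
CPU/GPU crossover.

Each mapping-path cost is modeled as a plane a·n_v + b·n_c + c in the mesh
vertex count n_v and surface cube count n_c.  Subtracting the planes gives
the inequality β_c·n_c < β_v·n_v + β_0 under which the batched
(shader-style) path wins; solving it at the largest benchmarked mesh gives
the largest favorable cube count.
"""

import octodeform as od

samples = od.paper_samples()
print(f"{len(samples)} unique timing samples "
      f"(n_v from {min(s.n_v for s in samples):,} to {max(s.n_v for s in samples):,}; "
      f"n_c from {min(s.n_c for s in samples)} to {max(s.n_c for s in samples)})")

cpu = od.fit_plane(samples, "cpu_map")
gpu = od.fit_plane(samples, "gpu_remaining")
print(f"CPU path: t = {cpu.a:.3e}·n_v + {cpu.b:.3e}·n_c + {cpu.c:.3f} ms  "
      f"(R² = {cpu.r_squared:.3f})")
print(f"GPU path: t = {gpu.a:.3e}·n_v + {gpu.b:.3e}·n_c + {gpu.c:.3f} ms  "
      f"(R² = {gpu.r_squared:.3f})")

cond = od.crossover(cpu, gpu)
print(f"batched path faster when {cond.beta_c:.3e}·n_c < "
      f"{cond.beta_v:.3e}·n_v + {cond.beta_0:.3f}")
n_v = 256_904
print(f"at n_v = {n_v:,}: batched mapping predicted faster for "
      f"n_c <= {od.max_cubes_for_gpu(cond, n_v)} surface cubes")
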