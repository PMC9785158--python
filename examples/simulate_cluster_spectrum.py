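"""Estimate the track-cluster spectrum of a targeted microbeam irradiation.

Each nucleus is aimed at with five single ions (corners + centre of a 4 µm
square); beam scatter (4 µm FWHM), counter miscounting and the elliptical
nucleus outline decide which tracks actually cross the nucleus and which of
them are too close to resolve as separate foci.
"""

from foci_kinetics import estimate_cluster_spectrum

spectrum = estimate_cluster_spectrum("p_3MeV", n_nuclei=10_000, seed=42)

print("mean clusters per nucleus, by cluster size:")
for n in spectrum.sizes:
    print(f"  {n}-track clusters: k_bar({n}) = {spectrum.k_bar[n]:.3f}")
print(f"mean tracks inside the nucleus: {spectrum.mean_tracks:.3f}")
print(f"sum of n * k_bar(n):            {spectrum.track_weighted_sum:.3f}")

# The two numbers above agree exactly: clusters partition the in-nucleus
# tracks.  The total is slightly below 5 because beam scatter puts some
# tracks outside the nucleus and the counter sometimes delivers 0 or 2 ions.
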