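"""Closed-loop oxygen-saturation recovery on a synthetic tube phantom.

A blood-filled tube with known 96 percent sO2 crosses the imaging plane
at three depths.  Forward photoacoustic images are synthesized from the
simulated fluence maps; recovery then unmixes the images with and
without fluence compensation.  The printed table shows that compensation
removes the depth-dependent bias of the raw spectral estimate.
"""

from oxylight.validation import closed_loop_tube_phantom

result = closed_loop_tube_phantom(
    depths_mm=(5.0, 10.0, 15.0),
    so2_percent=96.0,
    snr_db_list=(None, 10.0),
    n_photons=600_000,
    seed=7,
)

print(f"ground-truth tube sO2: {result['truth_so2']:.0f}%")
for res in result["results"]:
    label = (
        "noise-free"
        if res["snr_db"] is None
        else f"{res['snr_db']:.0f} dB SNR, {res['n_frames']}-frame average"
    )
    print(f"\n{label}:")
    print("  depth   compensated   uncompensated")
    for d, c, u in zip(
        result["depths_mm"], res["compensated"], res["uncompensated"]
    ):
        print(f"  {d:4.0f} mm   {c:7.1f}%      {u:7.1f}%")
# compensated values should sit near 96% at every depth; uncompensated
# values drift with depth because the two wavelengths' fluence decays
# differ
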