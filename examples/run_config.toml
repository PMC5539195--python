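# Complete run configuration for `plasmonet simulate --config ...`.
# CLI flags override values given here.

[arena]
# Either a packaged fixture name ...
fixture = "ridge"          # "triangle" | "ridge"
# ... or explicit raster/CSV inputs (uncomment to use):
# mask = "arena_mask.pgm"          # grey > 0 = habitable
# heightfield = "terrain.pgm"      # 8-bit greyscale, intensity = elevation
# sites = "sites.csv"              # header: region_id,name,row,col

[sim]
steps = 2000
init_density = 0.5         # inoculation coverage d0
# target_population = 6000 # overrides init_density when set
sensor_angle = 45.0        # SA, degrees
rotation_angle = 45.0      # RA, degrees
sensor_offset = 9.0        # SO, cells
step_size = 1.0            # SS, cells
deposit = 5.0              # D, trail units per successful move
decay = 0.1                # rho, trail fraction lost per step
diffusion_kernel = 3       # odd window size
site_stimulus = 255.0      # w_f, trail units projected per site per step
height_weight = 10.0       # w_h, sensing penalty per unit elevation
max_height = 1.0           # impassable-elevation cutoff (1.0 disables)
growth_window = 9
growth_min = 1
growth_max = 10
growth_interval = 5
shrink_window = 5
shrink_min = 1
shrink_interval = 5

[extract]
source = "trail"           # "trail" | "occupancy"
# tau = 2.5                # binarization threshold (default: deposit/2)
capture_radius = 5.0       # cells, for sites outside the digitized material
strict_steiner = false     # true: at most one junction between regions

[run]
replicates = 20            # seeded replicate simulations
seed = 0                   # replicate i uses seed + i
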