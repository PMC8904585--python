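# choromel=0.1.0 config=7b5a185afff9 seed=20
sector,mean_choroidal_thickness_um,mean_mech_thickness_um,mean_occupancy,n_valid_px
whole,233.0256233,89.58680476,0.4284930618,4345
center,261.6010461,125.5430338,0.5361404435,701
superior,227.1573868,96.26466221,0.4844930176,898
inferior,226.9868421,95.9130117,0.4454104148,912
nasal,228.8839318,85.63402249,0.4222997326,919
temporal,227.0714026,53.15081967,0.2655891332,915
outer_ring,227.5285401,82.66986828,0.4047520625,3644
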