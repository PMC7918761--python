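# Default kinetic parameter table for the methionine-cycle model.
# Units: vmax µM/h (AHCY: vmax = forward rate constant h⁻¹, alpha = reverse
# rate constant µM⁻¹·h⁻¹; CBS: vmax = rate constant h⁻¹); km/ki/ka/km2 µM.
# Values are package defaults giving a plausible hepatic operating point;
# they are not literature constants.
# schema_version = 1

[pools]
fivemthf = 5.2
betaine = 50.0
adenosine = 1.0

[MATI]
vmax = 180.0
km = 41.0
ki = 50.0

[MATII]
vmax = 100.0
km = 4.0
ki = 60.0

[MATIII]
vmax = 120.0
km = 300.0
ka = 360.0
alpha = 6.0

[GNMT]
vmax = 200.0
km = 100.0
ki = 18.0

[DNMT]
vmax = 150.0
km = 30.0
ki = 10.0

[AHCY]
vmax = 40.0
alpha = 2.0

[CBS]
vmax = 40.0
ka = 90.0

[MTR]
vmax = 80.0
km = 1.0
km2 = 25.0

[BHMT]
vmax = 90.0
km = 12.0
km2 = 100.0
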