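catalyst,ligand,active_catalyst_code,percent_buried_volume,sterimol_B1,sterimol_B5,sterimol_L,pyramidalization,sasa,volume
[Ir(OMe)(cod)]2,dtbpy,1,54.3,4.12,7.85,9.40,12.5,612.0,734.0
[Ir(Cl)(cod)]2,dtbpy,1,54.3,4.12,7.85,9.40,12.5,612.0,734.0
[Ir(OH)(cod)]2,dtbpy,1,54.3,4.12,7.85,9.40,12.5,612.0,734.0
[Ir(OMe)(cod)]2,bpy,2,52.1,3.95,7.10,9.05,11.8,586.0,701.0
[Ir(OMe)(cod)]2,tmphen,3,56.0,4.30,8.20,9.75,13.1,640.0,768.0
[Ir(OMe)(cod)]2,none,4,48.7,3.60,6.40,8.20,9.4,548.0,655.0
[Ir(OMe)(cod)]2,cod,4,48.7,3.60,6.40,8.20,9.4,548.0,655.0
[Ir(Cl)(cod)]2,dppe,5,57.9,4.55,8.60,10.10,14.2,668.0,802.0
[Ir(OMe)(cod)]2,PMe3,6,50.2,3.75,6.80,8.60,10.6,562.0,676.0
[Cp*RuCl2]2,none,7,51.5,3.88,7.00,8.85,11.0,574.0,689.0
[Cp*RuCl]4,none,7,51.5,3.88,7.00,8.85,11.0,574.0,689.0
[Cp*RuCl2]2,AsPh3,8,58.6,4.62,8.75,10.25,14.8,676.0,815.0
[Cp*RuCl]4,AsPh3,8,58.6,4.62,8.75,10.25,14.8,676.0,815.0
Cp*Rh(C6Me6),none,9,53.0,4.05,7.45,9.20,12.0,598.0,718.0
[RhCl(coe)2]2,PMe3,10,49.4,3.68,6.60,8.40,10.0,555.0,665.0
[RhCl(coe)2]2,none,11,47.8,3.52,6.20,8.05,9.0,540.0,645.0
[Ir(Cl)(cod)]2,AsPh3,12,59.2,4.70,8.90,10.40,15.1,684.0,824.0
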