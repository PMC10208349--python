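region,year,class,kind,area_ha
Palawan,1988,mangrove,observed,51438.2
Palawan,1993,mangrove,observed,50045.3
Palawan,1998,mangrove,observed,48745.3
Palawan,2003,mangrove,observed,52961.5
Palawan,2008,mangrove,observed,53877.0
Palawan,2013,mangrove,observed,55302.4
Palawan,2018,mangrove,observed,59774.2
Palawan,2020,mangrove,observed,60033.8
Palawan,1998,non_mangrove,observed,1375197.7
Palawan,2018,non_mangrove,observed,1364168.1
Palawan,2020,non_mangrove,observed,1363909.2
PPC,1988,mangrove,observed,2876.3
PPC,1998,mangrove,observed,5634.2
PPC,2003,mangrove,observed,5922.7
PPC,2008,mangrove,observed,6621.4
PPC,2013,mangrove,observed,6738.1
PPC,2018,mangrove,observed,6709.4
PPC,2020,mangrove,observed,6601.8
Taytay,1988,mangrove,observed,3865.1
Taytay,1998,mangrove,observed,6003.4
Taytay,2008,mangrove,observed,7591.8
Taytay,2013,mangrove,observed,7351.5
Taytay,2018,mangrove,observed,7285.1
Taytay,2020,mangrove,observed,7103.6
Aborlan,1988,mangrove,observed,1363.4
Aborlan,1993,mangrove,observed,1287.7
Aborlan,1998,mangrove,observed,1591.8
Aborlan,2008,mangrove,observed,1697.6
Aborlan,2013,mangrove,observed,1842.5
Aborlan,2018,mangrove,observed,1740.3
Aborlan,2020,mangrove,observed,1839.7
Palawan,2013,mangrove,projected,52414.5
Palawan,2030,mangrove,projected,64946.3
Palawan,2050,mangrove,projected,66972.1
Palawan,2030,non_mangrove,projected,1302149.6
Palawan,2050,non_mangrove,projected,1265498.0
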