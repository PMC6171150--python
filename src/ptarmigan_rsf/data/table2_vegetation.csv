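vegetation_class,codes,used,available
Exposed alpine ridges,12,60,460
Bilberry-low fern birch forest,6,366,1481
Wet mires sedge swamps and reed beds,11,147,633
Fresh heather and dwarf-shrub communities,17,4410,11380
Graminoid alpine ridge,13,216,894
Herb-rich meadows,18,572,994
Tall-grown lawn vegetation,10,666,1767
Crowberry birch forest,7,267,959
Lichen-rich birch forest,8,222,929
Lichen-rich heathland,15,145,1063
Heather- and grass-rich early snow patch communities,16,503,1924
Heather-rich alpine ridge,14,2240,6955
Lowland forest,1-5,711,3620
Bryophyte late snow patch vegetation,20,207,1100
Grass and dwarf willow snow-patch vegetation,19,94,742
Ombrotrophic bog and low-grown lawn vegetation,9,1320,3248
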