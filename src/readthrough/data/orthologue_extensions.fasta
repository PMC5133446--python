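>human synthetic clade=mammal
WLEPLKAASGNVQKTRCRL
>mouse synthetic clade=mammal
WLEPLKAASGNVQKSRCRL
>rat synthetic clade=mammal
WLEPLKAASGNVQKSRCRL
>cow synthetic clade=mammal
WLEPLKTASGNVQKTRCRL
>dog synthetic clade=mammal
WLEPLKAASGSVQKTRCRL
>pig synthetic clade=mammal
WLEPLKAASGNVQKTRCRL
>chicken synthetic clade=non-mammal-vertebrate
WLEPLKAVSGNVQKTRSRL
>zebra_finch synthetic clade=non-mammal-vertebrate
WLEPLKAVSGNVQKTRSRL
>turtle synthetic clade=non-mammal-vertebrate
WLEPLKAASGNVQKTRSRL
>lizard synthetic clade=non-mammal-vertebrate
WLEPLKAASGNIQKTRSRL
>zebrafish synthetic clade=non-mammal-vertebrate
WLEPLKGASGNVQKTRSRL
>frog synthetic clade=other
WLEPLKAASGNVQKTRARL
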