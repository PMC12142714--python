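category	keyword
field	wild
field	wild caught
field	wild-caught
field	field
field	field collected
field	field-collected
field	trap
field	trapped
field	pheromone trap
field	light trap
field	collected from nature
field	free-living
field	natural population
laboratory	lab
laboratory	laboratory
laboratory	strain
laboratory	inbred
laboratory	isofemale
laboratory	culture
laboratory	cultured
laboratory	reared
laboratory	line
commercial	commercial
commercial	supplier
commercial	purchased
commercial	vendor
commercial	commercially obtained
managed_colony	colony
managed_colony	apiary
managed_colony	managed
managed_colony	hive
managed_colony	stock center
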