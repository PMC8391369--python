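<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="food_dishes" description="platillos preferidos del paciente">
    <category role="trigger">
      <pattern>COMIDA</pattern>
      <template><random>
        <li>¡Se me antoja! ¿Es cierto que tu platillo favorito es <get name="comida_favorita"/>?</li>
        <li>¿Qué platillo te encanta saborear?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ COMIDA</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>COMIDA _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COMIDA _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>PLATILLO</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PLATILLO</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>PLATILLO _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ PLATILLO _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>COMER</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COMER</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>COMER _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ COMER _</pattern>
      <template><srai>COMIDA</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Delicioso! ¿Quién preparaba <get name="comida_favorita"/> en tu casa?</li>
        <li>¿En qué ocasiones comías <get name="comida_favorita"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Gracias por decirme. ¿Qué comida disfrutas más?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>La buena comida trae buenos recuerdos. ¿Me cuentas de tu platillo preferido?</li>
        <li>Cocinar es un cariño. ¿Qué guiso te recuerda a tu casa?</li>
      </random></template>
    </category>
  </topic>
</aiml>
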